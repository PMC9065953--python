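"""Inversion genotype calling from low-coverage pileup observations.

Each chromosomal inversion is scored as a single biallelic "super-locus":
panel sites inside the inversion are diagnostic for haplotype A vs B, and
because the inversion suppresses recombination a specimen's state is one of
AA, AB, BB across all of them.  Per read the emission model is a fixed
per-base error e:

    P(obs | allele x) = 1 − e   if obs == x,   e/3 otherwise
    P(obs | AB)       = ½ P(obs | A) + ½ P(obs | B)

Site (and read) contributions are summed in log space — sites are treated
as independent, which inside a non-recombining inversion overstates the
information content of the posterior but does not bias the ranking of
states; see the package methods note.  A uniform prior over the three
states yields the posterior; population priors belong to the assignment
stage, keeping calling and assignment separable.

Deamination handling (``damage_mode``):

* ``ignore`` — use every observation as-is.
* ``filter`` (default) — drop observations whose base could be the *other*
  panel allele deaminated: an observed T at a C/T site within
  ``damage_window`` of the 5' end, or an observed A at a G/A site within
  ``damage_window`` of the 3' end.  Conservative: costs a little coverage,
  removes the damage-driven bias toward T/A-carrying haplotypes.
* ``model`` — keep all observations but mix deamination into the emission:
  P(obs | C-allele) = (1−d)·P_err(obs|C) + d·P_err(obs|T) with
  d = d0̂·exp(−λ̂·dist5) taken from fitted damage parameters (mirrored for
  G at the 3' end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as itio
from .damage import DamageParams

GENOTYPE_STATES = ("AA", "AB", "BB")
NO_CALL = "no-call"
_UNIFORM = np.full(3, 1.0 / 3.0)


@dataclass(frozen=True)
class GenotypeConfig:
    error_rate: float = 0.01
    damage_mode: str = "filter"          # one of: ignore, filter, model
    damage_window: int = 5
    min_sites: int = 5
    call_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must lie in (0, 1)")
        if self.damage_mode not in ("ignore", "filter", "model"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")
        if self.damage_window < 0:
            raise ValueError("damage_window must be >= 0")
        if self.min_sites < 0:
            raise ValueError("min_sites must be >= 0")
        if not (1.0 / 3.0 < self.call_threshold <= 1.0):
            raise ValueError("call_threshold must lie in (1/3, 1]")


@dataclass(frozen=True)
class InversionGenotypeCall:
    specimen: str
    inversion_id: str
    posterior: tuple[float, float, float]   # P(AA), P(AB), P(BB)
    hard_call: str                           # AA / AB / BB / no-call
    n_sites_used: int
    n_reads_used: int

    @property
    def posterior_dict(self) -> dict[str, float]:
        return dict(zip(GENOTYPE_STATES, self.posterior))


def _check_bases(bases: np.ndarray) -> None:
    if not np.isin(bases, list(itio.VALID_BASES)).all():
        bad = sorted(set(bases) - itio.VALID_BASES)
        raise ValueError(f"invalid base(s) in observations: {bad}")


def _p_obs_given_allele(
    bases: np.ndarray,
    alleles: np.ndarray,
    e: float,
    dist5: Optional[np.ndarray],
    dist3: Optional[np.ndarray],
    damage: Optional[DamageParams],
) -> np.ndarray:
    """Vectorised P(observed base | true allele) per read.

    ``alleles`` may be a scalar-like array (one allele for all reads) or a
    per-read array when reads span sites with different alleles.
    """
    p = np.where(bases == alleles, 1.0 - e, e / 3.0)
    if damage is not None and damage.d0_hat > 0:
        # a true C may present as T (5' deamination), a true G as A (3')
        for ctx, prod, dist in (("C", "T", dist5), ("G", "A", dist3)):
            if dist is None:
                continue
            in_ctx = alleles == ctx
            if not np.any(in_ctx):
                continue
            d = damage.d0_hat * np.exp(-damage.lambda_hat * np.asarray(dist, float))
            p_prod = np.where(bases == prod, 1.0 - e, e / 3.0)
            p = np.where(in_ctx, (1.0 - d) * p + d * p_prod, p)
    return p


def site_log_likelihoods(
    bases: Sequence[str],
    allele_a: str,
    allele_b: str,
    cfg: GenotypeConfig,
    dist5: Optional[Sequence[int]] = None,
    dist3: Optional[Sequence[int]] = None,
    damage: Optional[DamageParams] = None,
) -> np.ndarray:
    """Log-likelihood triple (AA, AB, BB) for one panel site.

    Empty observations give (0, 0, 0).  ``damage`` is only consulted when
    ``cfg.damage_mode == "model"``.
    """
    if allele_a == allele_b:
        raise ValueError("site alleles must differ")
    for a in (allele_a, allele_b):
        if a not in itio.VALID_BASES:
            raise ValueError(f"invalid allele {a!r}")
    bases = np.asarray(bases, dtype="U1")
    if bases.size == 0:
        return np.zeros(3)
    _check_bases(bases)
    dmg = damage if cfg.damage_mode == "model" else None
    d5 = None if dist5 is None else np.asarray(dist5)
    d3 = None if dist3 is None else np.asarray(dist3)
    p_a = _p_obs_given_allele(bases, np.full(bases.shape, allele_a), cfg.error_rate, d5, d3, dmg)
    p_b = _p_obs_given_allele(bases, np.full(bases.shape, allele_b), cfg.error_rate, d5, d3, dmg)
    return np.array(
        [
            float(np.log(p_a).sum()),
            float(np.log(0.5 * p_a + 0.5 * p_b).sum()),
            float(np.log(p_b).sum()),
        ]
    )


def _damage_filter_mask(merged: pd.DataFrame, window: int) -> np.ndarray:
    """True for observations to KEEP under damage_mode='filter'."""
    base = merged["base"].to_numpy()
    a = merged["allele_A"].to_numpy()
    b = merged["allele_B"].to_numpy()
    is_ct_site = ((a == "C") & (b == "T")) | ((a == "T") & (b == "C"))
    is_ga_site = ((a == "G") & (b == "A")) | ((a == "A") & (b == "G"))
    drop = (
        (is_ct_site & (base == "T") & (merged["dist5"].to_numpy() < window))
        | (is_ga_site & (base == "A") & (merged["dist3"].to_numpy() < window))
    )
    return ~drop


def _posterior_from_loglik(loglik: np.ndarray) -> np.ndarray:
    shifted = loglik - loglik.max()
    w = np.exp(shifted)
    return w / w.sum()


def genotype_inversion(
    obs: pd.DataFrame,
    inversion_panel: pd.DataFrame,
    cfg: GenotypeConfig,
    damage: Optional[DamageParams] = None,
    specimen: Optional[str] = None,
) -> InversionGenotypeCall:
    """Call one inversion for one specimen.

    ``obs`` holds that specimen's observations (any sites; they are joined
    to the inversion's panel sites here), ``inversion_panel`` the panel rows
    of a single inversion.
    """
    if len(inversion_panel) == 0:
        raise ValueError("inversion panel is empty")
    inv_ids = inversion_panel["inversion_id"].unique()
    if len(inv_ids) != 1:
        raise ValueError("genotype_inversion expects sites of a single inversion")
    inversion_id = str(inv_ids[0])
    if specimen is None:
        specimen = str(obs["specimen"].iloc[0]) if len(obs) else ""

    merged = obs.merge(
        inversion_panel[["chrom", "pos", "allele_A", "allele_B"]],
        on=["chrom", "pos"],
        how="inner",
    )
    if cfg.damage_mode == "filter" and len(merged):
        merged = merged[_damage_filter_mask(merged, cfg.damage_window)]

    n_reads = int(len(merged))
    if n_reads == 0:
        return InversionGenotypeCall(
            specimen=specimen, inversion_id=inversion_id,
            posterior=tuple(_UNIFORM), hard_call=NO_CALL,
            n_sites_used=0, n_reads_used=0,
        )

    bases = merged["base"].to_numpy(dtype="U1")
    _check_bases(bases)
    dmg = damage if cfg.damage_mode == "model" else None
    d5 = merged["dist5"].to_numpy()
    d3 = merged["dist3"].to_numpy()
    e = cfg.error_rate
    p_a = _p_obs_given_allele(bases, merged["allele_A"].to_numpy(), e, d5, d3, dmg)
    p_b = _p_obs_given_allele(bases, merged["allele_B"].to_numpy(), e, d5, d3, dmg)
    # summing per-read logs across all sites == summing per-site triples
    loglik = np.array(
        [
            float(np.log(p_a).sum()),
            float(np.log(0.5 * p_a + 0.5 * p_b).sum()),
            float(np.log(p_b).sum()),
        ]
    )
    posterior = _posterior_from_loglik(loglik)
    n_sites = int(merged[["chrom", "pos"]].drop_duplicates().shape[0])

    best = int(np.argmax(posterior))
    if posterior[best] >= cfg.call_threshold and n_sites >= cfg.min_sites:
        hard = GENOTYPE_STATES[best]
    else:
        hard = NO_CALL
    return InversionGenotypeCall(
        specimen=specimen, inversion_id=inversion_id,
        posterior=tuple(float(x) for x in posterior), hard_call=hard,
        n_sites_used=n_sites, n_reads_used=n_reads,
    )


DamageBySpecimen = Union[None, DamageParams, dict]


def genotype_all(
    obs: pd.DataFrame,
    panel: pd.DataFrame,
    cfg: GenotypeConfig,
    damage: DamageBySpecimen = None,
    specimens: Optional[Sequence[str]] = None,
) -> list[InversionGenotypeCall]:
    """One call per (specimen, inversion) pair in the panel.

    ``damage`` may be a single :class:`DamageParams` for all specimens or a
    mapping specimen -> params (used only under ``damage_mode='model'``).
    """
    itio.validate_panel(panel)
    inversions = list(dict.fromkeys(panel["inversion_id"]))
    if specimens is None:
        specimens = sorted(obs["specimen"].unique()) if len(obs) else []

    by_specimen = {
        str(s): grp for s, grp in obs.groupby("specimen", sort=False)
    } if len(obs) else {}
    by_inversion = {inv: grp for inv, grp in panel.groupby("inversion_id", sort=False)}
    empty_obs = obs.iloc[0:0]

    calls: list[InversionGenotypeCall] = []
    for s in specimens:
        s = str(s)
        s_obs = by_specimen.get(s, empty_obs)
        dmg = damage.get(s) if isinstance(damage, dict) else damage
        for inv in inversions:
            calls.append(
                genotype_inversion(s_obs, by_inversion[inv], cfg, damage=dmg,
                                   specimen=s)
            )
    return calls


def calls_to_frame(calls: Iterable[InversionGenotypeCall]) -> pd.DataFrame:
    """Tabulate calls in the output TSV layout."""
    rows = [
        (
            c.specimen, c.inversion_id, c.posterior[0], c.posterior[1],
            c.posterior[2], c.hard_call, c.n_sites_used, c.n_reads_used,
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=itio.CALLS_COLUMNS)


def calls_from_frame(df: pd.DataFrame) -> list[InversionGenotypeCall]:
    """Inverse of :func:`calls_to_frame` (e.g. after reading a calls TSV)."""
    return [
        InversionGenotypeCall(
            specimen=str(r.specimen), inversion_id=str(r.inversion_id),
            posterior=(float(r.p_AA), float(r.p_AB), float(r.p_BB)),
            hard_call=str(r.hard_call), n_sites_used=int(r.n_sites_used),
            n_reads_used=int(r.n_reads_used),
        )
        for r in df.itertuples(index=False)
    ]
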