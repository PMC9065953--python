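"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates, per specimen:

* inversion genotypes drawn under Hardy–Weinberg equilibrium from
  population-specific haplotype-B frequencies;
* per-site read counts ~ Poisson(coverage);
* each read carries one of the two chromosomes uniformly, its base is then
  subject to terminal cytosine deamination — C→T with probability
  ``d0·exp(−λ_d·dist5)`` and G→A with ``d0·exp(−λ_d·dist3)`` — followed by
  uniform sequencing error ``e`` (to each of the other three bases with
  probability ``e/3``);
* fragment lengths lognormal, site position uniform within the fragment
  (so ``dist5 + dist3 = read_len − 1``);
* radiocarbon measurements drawn around an interpolated curve value plus a
  reservoir offset ΔR.

Deamination is applied before sequencing error, matching the biochemical
order (post-mortem damage precedes the sequencer).  A single global seed
drives everything; per-specimen substreams are derived from the specimen
index so partial cohorts reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as itio
from .calibrate import CalibrationCurve, RadiocarbonDate, SKREI_DELTA_R, STATIONARY_DELTA_R

GENOTYPE_LABELS = ("AA", "AB", "BB")
DEFAULT_INVERSIONS = ("LG1", "LG2", "LG7", "LG12")

#: candidate populations: migratory Northeast Arctic cod and the two
#: stationary coastal groups distinguished in ecotype assignment.
DEFAULT_POPULATIONS = ("NEAC", "Lofoten_Coastal", "West_Coastal")

_BASES = np.array(["A", "C", "G", "T"])
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
# damage-confusable pairs: an observed T may be a deaminated C, an observed
# A a deaminated G.
_CONFUSABLE_PAIRS = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]
_TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the read-level generative model.

    coverage_mean
        Expected reads per diagnostic site (Poisson λ).
    error_rate
        Per-base sequencing error e.
    damage_amplitude, damage_decay
        Terminal deamination probability at the read end (d0) and its
        per-base exponential decay constant (λ_d).
    fragment_len_meanlog, fragment_len_sdlog
        Lognormal fragment-length parameters (defaults give a mean of
        ~58 bp, typical of ancient DNA extracts).
    """

    coverage_mean: float = 0.5
    error_rate: float = 0.01
    damage_amplitude: float = 0.25
    damage_decay: float = 0.3
    fragment_len_meanlog: float = 4.0
    fragment_len_sdlog: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_mean",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("error_rate", "damage_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.damage_decay <= 0:
            raise ValueError("damage_decay must be > 0")
        if self.fragment_len_sdlog < 0:
            raise ValueError("fragment_len_sdlog must be >= 0")


def _specimen_rng(cfg_seed: int, index: int) -> np.random.Generator:
    """Deterministic substream for the ``index``-th specimen."""
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=(index,)))


def make_panel(
    n_sites_per_inversion: int,
    inversions: Sequence[str] = DEFAULT_INVERSIONS,
    seed: int = 0,
    confusable_fraction: float = 0.5,
) -> pd.DataFrame:
    """Draw a synthetic inversion-diagnostic SNP panel.

    A ``confusable_fraction`` of sites get C/T or G/A allele pairs (whose
    genotyping is entangled with deamination), the rest transversions.
    """
    if n_sites_per_inversion < 1:
        raise ValueError("n_sites_per_inversion must be >= 1")
    if not 0.0 <= confusable_fraction <= 1.0:
        raise ValueError("confusable_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for inv in inversions:
        pos = np.sort(
            rng.choice(np.arange(1, 10_000_001), size=n_sites_per_inversion,
                       replace=False)
        )
        for p in pos:
            if rng.random() < confusable_fraction:
                a, b = _CONFUSABLE_PAIRS[rng.integers(len(_CONFUSABLE_PAIRS))]
            else:
                a, b = _TRANSVERSION_PAIRS[rng.integers(len(_TRANSVERSION_PAIRS))]
            records.append((inv, inv, int(p), a, b))
    panel = pd.DataFrame(records, columns=itio.PANEL_COLUMNS)
    return itio.validate_panel(panel)


def _draw_genotypes(
    inversions: Sequence[str],
    population: str,
    freqs: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, int]:
    """HWE draw: number of B alleles per inversion (0, 1 or 2)."""
    sub = freqs[freqs["population"] == population]
    if sub.empty:
        raise KeyError(f"population {population!r} absent from frequency table")
    lookup = dict(zip(sub["inversion_id"], sub["freq_B"]))
    genotypes = {}
    for inv in inversions:
        if inv not in lookup:
            raise KeyError(
                f"no frequency for population {population!r}, inversion {inv!r}"
            )
        genotypes[inv] = int(rng.binomial(2, float(lookup[inv])))
    return genotypes


def simulate_specimen(
    specimen: str,
    truth_population: str,
    panel: pd.DataFrame,
    freqs: pd.DataFrame,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    true_cal_age: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one specimen; returns (truth table, observations table)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    inversions = list(dict.fromkeys(panel["inversion_id"]))
    genotypes = _draw_genotypes(inversions, truth_population, freqs, rng)

    truth = pd.DataFrame(
        {
            "specimen": specimen,
            "population": truth_population,
            "inversion_id": inversions,
            "genotype": [GENOTYPE_LABELS[genotypes[i]] for i in inversions],
            "true_cal_age": np.nan if true_cal_age is None else float(true_cal_age),
        }
    )

    n_sites = len(panel)
    counts = rng.poisson(cfg.coverage_mean, size=n_sites)
    n_reads = int(counts.sum())
    if n_reads == 0:
        obs = pd.DataFrame(columns=itio.OBS_COLUMNS).astype(
            {"pos": int, "dist5": int, "dist3": int, "read_len": int}
        )
        return truth, obs

    site_idx = np.repeat(np.arange(n_sites), counts)
    inv_per_site = panel["inversion_id"].to_numpy()
    g_per_site = np.array([genotypes[i] for i in inv_per_site], dtype=float)
    allele_a = np.array([_BASE_CODE[b] for b in panel["allele_A"]])
    allele_b = np.array([_BASE_CODE[b] for b in panel["allele_B"]])

    # chromosome choice: a read carries haplotype B with probability g/2
    carries_b = rng.random(n_reads) < g_per_site[site_idx] / 2.0
    base = np.where(carries_b, allele_b[site_idx], allele_a[site_idx])

    read_len = np.maximum(
        1,
        np.rint(
            rng.lognormal(cfg.fragment_len_meanlog, cfg.fragment_len_sdlog, n_reads)
        ).astype(int),
    )
    dist5 = rng.integers(0, read_len)  # uniform insertion point in the fragment
    dist3 = read_len - 1 - dist5

    # deamination first (biochemical order), then sequencing error
    d0, lam = cfg.damage_amplitude, cfg.damage_decay
    is_c = base == _BASE_CODE["C"]
    flip_c = is_c & (rng.random(n_reads) < d0 * np.exp(-lam * dist5))
    is_g = base == _BASE_CODE["G"]
    flip_g = is_g & (rng.random(n_reads) < d0 * np.exp(-lam * dist3))
    base = base.copy()
    base[flip_c] = _BASE_CODE["T"]
    base[flip_g] = _BASE_CODE["A"]

    err = rng.random(n_reads) < cfg.error_rate
    shift = rng.integers(1, 4, size=n_reads)
    base = np.where(err, (base + shift) % 4, base)

    obs = pd.DataFrame(
        {
            "specimen": specimen,
            "chrom": panel["chrom"].to_numpy()[site_idx],
            "pos": panel["pos"].to_numpy()[site_idx],
            "base": _BASES[base],
            "dist5": dist5,
            "dist3": dist3,
            "read_len": read_len,
        }
    )
    return truth, obs


def simulate_cohort(
    populations: Sequence[tuple[str, str]],
    panel: pd.DataFrame,
    freqs: pd.DataFrame,
    cfg: SimulationConfig,
    true_cal_ages: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate many specimens; ``populations`` is (specimen, population) pairs.

    Each specimen gets its own deterministic substream keyed by its index,
    so identical seeds reproduce byte-identical cohorts and prefixes of a
    cohort are stable under extension.
    """
    truths, obss = [], []
    for i, (specimen, population) in enumerate(populations):
        rng = _specimen_rng(cfg.seed, i)
        age = None if true_cal_ages is None else true_cal_ages[i]
        truth, obs = simulate_specimen(
            specimen, population, panel, freqs, cfg, rng=rng, true_cal_age=age
        )
        truths.append(truth)
        obss.append(obs)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=itio.TRUTH_COLUMNS
    )
    obs_frames = [o for o in obss if len(o)]
    if obs_frames:
        obs = pd.concat(obs_frames, ignore_index=True)
    else:
        obs = pd.DataFrame(columns=itio.OBS_COLUMNS).astype(
            {"pos": int, "dist5": int, "dist3": int, "read_len": int}
        )
    return truth, obs


def simulate_radiocarbon(
    true_cal_age: float,
    curve: CalibrationCurve,
    sigma_meas: float,
    delta_r: float = 0.0,
    sigma_delta_r: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    label: str = "",
) -> RadiocarbonDate:
    """Forward model of the calibration likelihood: draw one measurement.

    measured ~ Normal(μ_curve(t) + ΔR, sqrt(σ_meas² + σ_curve²(t))).
    """
    if not curve.contains(true_cal_age):
        raise ValueError(
            f"true_cal_age {true_cal_age} outside curve support "
            f"[{curve.cal_min}, {curve.cal_max}]"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = float(curve.mu_at(true_cal_age))
    sd = float(np.sqrt(sigma_meas ** 2 + curve.sigma_at(true_cal_age) ** 2))
    measured = float(rng.normal(mu + delta_r, sd))
    return RadiocarbonDate(
        measured_age=measured,
        sigma_meas=float(sigma_meas),
        delta_r=float(delta_r),
        sigma_delta_r=float(sigma_delta_r),
        label=label,
    )


def make_wiggly_curve(
    cal_min: float = 0.0,
    cal_max: float = 6000.0,
    step: float = 5.0,
    amplitude: float = 150.0,
    period: float = 800.0,
    sigma_curve: float = 12.0,
) -> CalibrationCurve:
    """Synthetic calibration curve: unit slope plus a sinusoidal wiggle.

    Deliberately non-monotone in places (as real curves are), which
    exercises multimodal posteriors and multi-interval HPD sets.
    """
    cal = np.arange(cal_min, cal_max + step / 2, step)
    c14 = cal + amplitude * np.sin(2 * np.pi * cal / period)
    sig = np.full_like(cal, float(sigma_curve))
    return CalibrationCurve(cal_bp=cal, c14_age=c14, sigma=sig)


def identity_curve(
    cal_min: float = 0.0, cal_max: float = 10_000.0, sigma_curve: float = 0.0
) -> CalibrationCurve:
    """Two-point curve with μ(t) = t — handy for analytic checks."""
    return CalibrationCurve(
        cal_bp=np.array([cal_min, cal_max]),
        c14_age=np.array([cal_min, cal_max]),
        sigma=np.array([sigma_curve, sigma_curve]),
    )


def _freq_frame(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [
        (pop, inv, f)
        for pop, per_inv in values.items()
        for inv, f in per_inv.items()
    ]
    return itio.validate_frequencies(
        pd.DataFrame(rows, columns=itio.FREQ_COLUMNS)
    )


def strong_differentiation_frequencies() -> pd.DataFrame:
    """Frequency table for the documented parameter-recovery scenario.

    Three populations on four inversions with near-fixed (0.98 vs 0.02)
    differences at two to three loci per population pair — the regime in
    which four inversion genotypes suffice for confident three-way
    assignment.  Synthetic; not measured cod frequencies.
    """
    return _freq_frame(
        {
            "NEAC": {"LG1": 0.98, "LG2": 0.98, "LG7": 0.02, "LG12": 0.98},
            "Lofoten_Coastal": {"LG1": 0.02, "LG2": 0.98, "LG7": 0.98, "LG12": 0.02},
            "West_Coastal": {"LG1": 0.02, "LG2": 0.02, "LG7": 0.02, "LG12": 0.02},
        }
    )


def illustrative_frequencies() -> pd.DataFrame:
    """Illustrative placeholder haplotype-B frequencies.

    Shaped like published ecotype contrasts (the migratory ecotype nearly
    fixed for the alternative arrangement at LG1, coastal groups at low
    frequency) but NOT actual estimates; supply real modern reference
    frequencies for real analyses.
    """
    return _freq_frame(
        {
            "NEAC": {"LG1": 0.95, "LG2": 0.80, "LG7": 0.30, "LG12": 0.90},
            "Lofoten_Coastal": {"LG1": 0.15, "LG2": 0.60, "LG7": 0.80, "LG12": 0.25},
            "West_Coastal": {"LG1": 0.05, "LG2": 0.15, "LG7": 0.70, "LG12": 0.15},
        }
    )
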