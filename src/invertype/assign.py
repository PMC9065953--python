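"""Population (ecotype) assignment from inversion genotypes.

Given a specimen's genotype at each inversion and modern haplotype-B
frequencies f per candidate population, the probability of the observed
genotype under a population follows Hardy–Weinberg equilibrium:

    P(AA | f) = (1 − f)²,   P(AB | f) = 2 f (1 − f),   P(BB | f) = f².

Inversions are treated as independent loci, so the likelihood of a
specimen under a population is the product over its called inversions, and
the posterior over populations follows from Bayes' rule with a (by default
uniform) prior — a naive-Bayes classifier over inversion genotypes.  In
``soft`` mode the genotype-calling posterior is marginalised instead of
plugging in the hard call:

    P(data | pop) = Π_inv Σ_G P(G | call posterior) · P(G | f_pop,inv).

Per-inversion probabilities are floored (default 1e-9) before taking logs
so a population with a fixed frequency (f ∈ {0, 1}) is not annihilated by
a single discordant — possibly erroneous or damage-driven — call.

Candidate populations are whatever the frequency table lists; nothing in
this module hard-codes the three cod groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as itio
from .genotype import GENOTYPE_STATES, NO_CALL, InversionGenotypeCall

UNASSIGNED = "unassigned"


def genotype_prob_under_pop(genotype: str, f_b: float) -> float:
    """Hardy–Weinberg probability of a genotype given haplotype-B frequency."""
    if not 0.0 <= f_b <= 1.0:
        raise ValueError("f_b must lie in [0, 1]")
    if genotype == "AA":
        return (1.0 - f_b) ** 2
    if genotype == "AB":
        return 2.0 * f_b * (1.0 - f_b)
    if genotype == "BB":
        return f_b ** 2
    raise ValueError(f"invalid genotype label {genotype!r}")


@dataclass(frozen=True)
class AssignConfig:
    threshold: float = 0.95
    mode: str = "hard"              # hard | soft
    prob_floor: float = 1e-9
    prior: Optional[Mapping[str, float]] = None   # None -> uniform

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"unknown assignment mode {self.mode!r}")
        if not 0.0 < self.prob_floor < 1.0:
            raise ValueError("prob_floor must lie in (0, 1)")
        if self.prior is not None:
            total = sum(self.prior.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("prior must sum to 1")


@dataclass(frozen=True)
class EcotypeAssignment:
    specimen: str
    posterior: dict[str, float]
    label: str
    contributions: dict[tuple[str, str], float]  # (population, inversion) -> log P
    n_inversions_used: int


def _frequency_lookup(freqs: pd.DataFrame) -> tuple[list[str], dict]:
    itio.validate_frequencies(freqs)
    populations = list(dict.fromkeys(freqs["population"]))
    table = {
        (str(r.population), str(r.inversion_id)): float(r.freq_B)
        for r in freqs.itertuples(index=False)
    }
    return populations, table


def assign_ecotype(
    calls: Sequence[InversionGenotypeCall],
    freqs: pd.DataFrame,
    cfg: AssignConfig = AssignConfig(),
) -> EcotypeAssignment:
    """Posterior over candidate populations for one specimen.

    No-call inversions are skipped; with no usable inversion at all the
    prior is returned and the specimen is labelled "unassigned".
    """
    populations, table = _frequency_lookup(freqs)
    if len(populations) < 2:
        raise ValueError("need at least two candidate populations")
    if not (1.0 / len(populations) < cfg.threshold <= 1.0):
        raise ValueError(
            f"threshold must lie in (1/{len(populations)}, 1]"
        )
    if cfg.prior is None:
        prior = {p: 1.0 / len(populations) for p in populations}
    else:
        if set(cfg.prior) != set(populations):
            raise ValueError("prior keys must match frequency-table populations")
        prior = {p: float(cfg.prior[p]) for p in populations}

    specimen = calls[0].specimen if calls else ""
    usable = [c for c in calls if c.hard_call != NO_CALL]

    contributions: dict[tuple[str, str], float] = {}
    if not usable:
        return EcotypeAssignment(
            specimen=specimen, posterior=dict(prior), label=UNASSIGNED,
            contributions=contributions, n_inversions_used=0,
        )

    log_post = {}
    for pop in populations:
        total = math.log(prior[pop]) if prior[pop] > 0 else -math.inf
        for call in usable:
            key = (pop, call.inversion_id)
            if key not in table:
                raise KeyError(
                    f"no frequency for population {pop!r}, "
                    f"inversion {call.inversion_id!r}"
                )
            f = table[key]
            if cfg.mode == "hard":
                p = genotype_prob_under_pop(call.hard_call, f)
            else:
                p = sum(
                    call.posterior_dict[g] * genotype_prob_under_pop(g, f)
                    for g in GENOTYPE_STATES
                )
            logp = math.log(max(p, cfg.prob_floor))
            contributions[key] = logp
            total += logp
        log_post[pop] = total

    m = max(log_post.values())
    weights = {p: math.exp(v - m) for p, v in log_post.items()}
    z = sum(weights.values())
    posterior = {p: w / z for p, w in weights.items()}

    best = max(populations, key=lambda p: posterior[p])
    label = best if posterior[best] >= cfg.threshold else UNASSIGNED
    return EcotypeAssignment(
        specimen=specimen, posterior=posterior, label=label,
        contributions=contributions, n_inversions_used=len(usable),
    )


@dataclass(frozen=True)
class CohortSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    n: int


def classify_cohort(assignments: Sequence[EcotypeAssignment]) -> CohortSummary:
    """Per-label counts and fractions over a cohort of assignments."""
    if not assignments:
        raise ValueError("need at least one assignment")
    labels = sorted({p for a in assignments for p in a.posterior}) + [UNASSIGNED]
    counts = {lab: 0 for lab in labels}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    n = len(assignments)
    fractions = {lab: c / n for lab, c in counts.items()}
    return CohortSummary(counts=counts, fractions=fractions, n=n)


def assignments_to_frame(assignments: Sequence[EcotypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments: one posterior column per population."""
    if not assignments:
        return pd.DataFrame(columns=["specimen", "label", "n_inversions_used"])
    populations = list(assignments[0].posterior)
    rows = []
    for a in assignments:
        row = {"specimen": a.specimen}
        for p in populations:
            row[f"p_{p}"] = a.posterior[p]
        row["label"] = a.label
        row["n_inversions_used"] = a.n_inversions_used
        rows.append(row)
    return pd.DataFrame(rows)
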