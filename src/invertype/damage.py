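"""Post-mortem deamination profiling and authenticity screening.

Ancient DNA carries cytosine deamination that shows up as C→T mismatches
near the 5' end of reads and G→A near the 3' end, with rates decaying
roughly exponentially with distance from the terminus.  This module
estimates those rate curves from panel-site observations, fits the
two-parameter decay r(k) = d0·exp(−λ·k), and flags specimens whose fitted
profile looks like authentic ancient DNA.

Mismatch attribution: at a site whose two panel alleles are C and T, an
observed T is ambiguous (real allele vs deaminated C), so such sites are
excluded from damage rates entirely.  Rates use only C-context sites (C is
a panel allele, T is not); within those, the denominator is restricted to
reads showing C or T — reads carrying the other allele tell us nothing
about cytosine deamination and would otherwise dilute the rate by the
allele frequency.  Mirrored for G→A at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_WINDOW = 25


@dataclass(frozen=True)
class DamageProfile:
    """Empirical terminal mismatch rates and fragment-length summary."""

    rate5_ct: np.ndarray       # C→T rate at distance k from the 5' end
    denom5: np.ndarray
    rate3_ga: np.ndarray       # G→A rate at distance k from the 3' end
    denom3: np.ndarray
    fragment_mean: float
    fragment_median: float
    fragment_sd: float
    window: int

    def to_frame(self) -> pd.DataFrame:
        """Long format: ``end  position  mismatch_rate  denominator``."""
        k = np.arange(self.window)
        return pd.DataFrame(
            {
                "end": ["5p"] * self.window + ["3p"] * self.window,
                "position": np.concatenate([k, k]),
                "mismatch_rate": np.concatenate([self.rate5_ct, self.rate3_ga]),
                "denominator": np.concatenate([self.denom5, self.denom3]),
            }
        )


@dataclass(frozen=True)
class DamageParams:
    """Fitted exponential-decay damage parameters."""

    d0_hat: float
    lambda_hat: float
    residual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d0_hat <= 1.0:
            raise ValueError("d0_hat must lie in [0, 1]")
        if self.lambda_hat < 0:
            raise ValueError("lambda_hat must be >= 0")


@dataclass(frozen=True)
class AuthenticityCall:
    authentic_like: bool
    rationale: str


def _context_counts(
    merged: pd.DataFrame,
    context_allele: str,
    product_base: str,
    dist_col: str,
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch numerators/denominators per distance for one read end."""
    has_context = (merged["allele_A"] == context_allele) | (
        merged["allele_B"] == context_allele
    )
    has_product = (merged["allele_A"] == product_base) | (
        merged["allele_B"] == product_base
    )
    usable = merged[has_context & ~has_product]
    informative = usable[usable["base"].isin([context_allele, product_base])]

    dist = informative[dist_col].to_numpy()
    in_window = dist < window
    dist = dist[in_window]
    is_product = (informative["base"].to_numpy() == product_base)[in_window]

    denom = np.bincount(dist, minlength=window)[:window].astype(float)
    numer = np.bincount(dist, weights=is_product.astype(float), minlength=window)[
        :window
    ]
    return numer, denom


def profile_damage(
    obs: pd.DataFrame, panel: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> DamageProfile:
    """Estimate terminal C→T / G→A rates and fragment-length summaries."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(obs) == 0:
        raise ValueError("cannot profile damage from empty observations")

    merged = obs.merge(
        panel[["chrom", "pos", "allele_A", "allele_B"]], on=["chrom", "pos"],
        how="inner",
    )
    if len(merged) == 0:
        raise ValueError("no observations overlap the panel")

    num5, den5 = _context_counts(merged, "C", "T", "dist5", window)
    num3, den3 = _context_counts(merged, "G", "A", "dist3", window)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), 0.0)
        rate3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), 0.0)

    lengths = merged["read_len"].to_numpy(dtype=float)
    return DamageProfile(
        rate5_ct=rate5,
        denom5=den5,
        rate3_ga=rate3,
        denom3=den3,
        fragment_mean=float(lengths.mean()),
        fragment_median=float(np.median(lengths)),
        fragment_sd=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        window=window,
    )


def fit_decay(profile: DamageProfile) -> DamageParams:
    """Weighted least-squares fit of r(k) = d0·exp(−λ·k) to the 5' series.

    Weights are the per-position denominators; d0 is constrained to [0, 1]
    and λ to be non-negative.
    """
    usable = profile.denom5 > 0
    if usable.sum() < 3:
        raise ValueError(
            f"need >=3 positions with data to fit decay, have {int(usable.sum())}"
        )
    k = np.arange(profile.window, dtype=float)[usable]
    r = profile.rate5_ct[usable]
    w = np.sqrt(profile.denom5[usable])

    if np.all(r == 0.0):
        return DamageParams(d0_hat=0.0, lambda_hat=0.0, residual=0.0)

    # log-linear initial guess from the strictly positive rates
    pos = r > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(k[pos], np.log(r[pos]), 1)
        lam0 = float(np.clip(-slope, 1e-3, 10.0))
        d00 = float(np.clip(np.exp(intercept), 1e-6, 1.0))
    else:
        lam0, d00 = 0.3, float(np.clip(r.max(), 1e-6, 1.0))

    def resid(theta):
        d0, lam = theta
        return w * (d0 * np.exp(-lam * k) - r)

    fit = least_squares(
        resid, x0=[d00, lam0], bounds=([0.0, 0.0], [1.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    d0_hat, lambda_hat = fit.x
    return DamageParams(
        d0_hat=float(np.clip(d0_hat, 0.0, 1.0)),
        lambda_hat=float(max(lambda_hat, 0.0)),
        residual=float(np.sum(fit.fun ** 2)),
    )


def authenticity_check(params: DamageParams, min_d0: float = 0.05) -> AuthenticityCall:
    """Flag a specimen whose damage profile is consistent with ancient DNA.

    "Authentic-like" means a terminal deamination amplitude of at least
    ``min_d0`` (boundary inclusive) together with a positive decay — i.e.
    elevated C→T mismatches concentrated at the read ends.  This is a
    screening heuristic, not proof of antiquity.
    """
    if params.d0_hat >= min_d0 and params.lambda_hat > 0:
        return AuthenticityCall(
            True,
            f"terminal C->T amplitude {params.d0_hat:.3f} >= {min_d0:.3f} with "
            f"positive decay (lambda={params.lambda_hat:.3f}): consistent with "
            "post-mortem deamination",
        )
    return AuthenticityCall(
        False,
        f"terminal C->T amplitude {params.d0_hat:.3f} (threshold {min_d0:.3f}) "
        f"with decay lambda={params.lambda_hat:.3f}: no terminal damage "
        "signature detected",
    )
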