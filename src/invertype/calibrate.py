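"""Marine radiocarbon calibration with reservoir offsets.

A radiocarbon determination is a measured age ``m`` (¹⁴C yr BP) with
uncertainty ``σ_m``.  For a marine sample the expected measurement at true
calendar age ``t`` is the marine calibration-curve mean plus a local
reservoir offset ΔR:

    E[m | t] = μ_curve(t) + ΔR

with all uncertainties pooled in quadrature,

    σ_tot²(t) = σ_m² + σ_ΔR² + σ_curve²(t).

The posterior over calendar ages on a 1-year grid under a uniform prior is

    p(t | m) ∝ exp(−(m − μ_curve(t) − ΔR)² / (2 σ_tot²(t))) / σ_tot(t),

normalised to sum to one.  Calibrated ranges are reported as highest
posterior density (HPD) sets: grid years are accumulated in order of
decreasing posterior mass until the requested coverage is reached, then
merged into contiguous intervals.  Because the curve is non-monotone, an
HPD set may consist of several intervals.

ΔR differs by ecotype here because migratory cod feed in the Barents Sea
while stationary cod feed along the Norwegian coast, i.e. in water masses
with different reservoir ages.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

#: (ΔR, σ_ΔR) reservoir offsets in ¹⁴C years for the migratory ecotype
#: (Northeast Arctic cod, Barents Sea feeding grounds) and the stationary
#: coastal ecotype (Norwegian coastal feeding grounds).
SKREI_DELTA_R: tuple[float, float] = (-144.0, 46.0)
STATIONARY_DELTA_R: tuple[float, float] = (-164.0, 29.0)

DEFAULT_HPD_LEVELS: tuple[float, ...] = (0.683, 0.954)


class CurveFormatError(ValueError):
    """Raised when a calibration-curve file cannot be parsed."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Calibration curve grid: calendar age vs ¹⁴C age with uncertainty.

    Stored sorted ascending in ``cal_bp`` regardless of input order; lookups
    between grid points interpolate linearly.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_bp, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if cal.ndim != 1 or cal.size < 2:
            raise CurveFormatError("calibration curve needs at least 2 grid points")
        if cal.size != c14.size or cal.size != sig.size:
            raise CurveFormatError("curve columns have unequal lengths")
        order = np.argsort(cal)
        cal, c14, sig = cal[order], c14[order], sig[order]
        if np.any(np.diff(cal) <= 0):
            raise CurveFormatError("duplicate cal BP values in calibration curve")
        if np.any(sig < 0):
            raise CurveFormatError("negative curve sigma")
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "sigma", sig)

    @property
    def cal_min(self) -> float:
        return float(self.cal_bp[0])

    @property
    def cal_max(self) -> float:
        return float(self.cal_bp[-1])

    def contains(self, t: float) -> bool:
        return self.cal_min <= t <= self.cal_max

    def mu_at(self, t):
        """Interpolated ¹⁴C age at calendar age(s) ``t``."""
        return np.interp(t, self.cal_bp, self.c14_age)

    def sigma_at(self, t):
        return np.interp(t, self.cal_bp, self.sigma)


@dataclass(frozen=True)
class RadiocarbonDate:
    """An uncalibrated marine ¹⁴C determination with its reservoir offset.

    ``sigma_meas`` may be zero on a stored record (e.g. a noise-free forward
    simulation); calibration itself requires it to be positive.
    """

    measured_age: float
    sigma_meas: float
    delta_r: float = 0.0
    sigma_delta_r: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma_meas < 0:
            raise ValueError("sigma_meas must be non-negative")
        if self.sigma_delta_r < 0:
            raise ValueError("sigma_delta_r must be non-negative")


@dataclass(frozen=True)
class HPDResult:
    """HPD set at one coverage level: intervals are closed [lo, hi] cal BP."""

    level: float
    intervals: tuple[tuple[int, int], ...]
    coverage: float

    @property
    def total_width(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.intervals)

    def contains(self, t: float) -> bool:
        return any(lo <= t <= hi for lo, hi in self.intervals)


@dataclass(frozen=True)
class CalibratedDensity:
    """Posterior over calendar ages on a 1-year grid, with HPD summaries."""

    cal_bp: np.ndarray
    mass: np.ndarray
    hpd: dict[float, HPDResult] = field(default_factory=dict)
    label: str = ""

    @property
    def mode(self) -> int:
        return int(self.cal_bp[int(np.argmax(self.mass))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.cal_bp, "mass": self.mass})


def read_curve(source: Union[str, Path, _stdio.TextIOBase]) -> CalibrationCurve:
    """Parse a calibration curve in the standard IntCal/Marine ``.14c`` layout.

    Lines starting with ``#`` are comments; data lines are comma- or
    whitespace-separated with at least three numeric columns
    (cal BP, ¹⁴C age, σ); extra columns (Δ¹⁴C etc.) are ignored.  Either
    input ordering is accepted; the curve is stored ascending in cal BP.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    cal, c14, sig = [], [], []
    seen: dict[float, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace(",", " ").split()
        if len(fields) < 3:
            raise CurveFormatError(
                f"line {lineno}: expected >=3 columns, got {len(fields)}"
            )
        try:
            values = [float(x) for x in fields[:3]]
        except ValueError as exc:
            raise CurveFormatError(f"line {lineno}: non-numeric field ({exc})") from exc
        if values[0] in seen:
            raise CurveFormatError(
                f"line {lineno}: duplicate cal BP value {values[0]:g} "
                f"(first seen on line {seen[values[0]]})"
            )
        seen[values[0]] = lineno
        cal.append(values[0])
        c14.append(values[1])
        sig.append(values[2])

    if len(cal) < 2:
        raise CurveFormatError(f"only {len(cal)} data rows; need at least 2")
    return CalibrationCurve(np.array(cal), np.array(c14), np.array(sig))


def write_curve(curve: CalibrationCurve, path: Union[str, Path],
                comment: str = "calibration curve") -> None:
    """Write a curve in the comma-separated ``.14c`` layout."""
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n# cal BP, 14C age BP, sigma\n")
        for t, m, s in zip(curve.cal_bp, curve.c14_age, curve.sigma):
            fh.write(f"{t:g},{m:g},{s:g}\n")


def hpd(cal_bp: np.ndarray, mass: np.ndarray, level: float) -> HPDResult:
    """Highest posterior density set by greedy mass ranking on the grid.

    Grid years are added in order of decreasing mass (ties broken toward
    older years, i.e. larger cal BP, for determinism) until the cumulative
    mass reaches ``level``; contiguous runs are merged into intervals and
    the attained coverage is reported.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("HPD level must lie in (0, 1)")
    cal_bp = np.asarray(cal_bp)
    mass = np.asarray(mass, dtype=float)
    if abs(mass.sum() - 1.0) > 1e-6:
        raise ValueError("mass vector must sum to 1")
    # lexsort: last key is primary -> descending mass, then descending cal BP
    order = np.lexsort((-cal_bp, -mass))
    cum = np.cumsum(mass[order])
    n_keep = int(np.searchsorted(cum, level) + 1)
    n_keep = min(n_keep, len(order))
    selected = np.sort(cal_bp[order[:n_keep]])
    coverage = float(cum[n_keep - 1])

    intervals: list[tuple[int, int]] = []
    start = prev = int(selected[0])
    for year in selected[1:]:
        year = int(year)
        if year == prev + 1:
            prev = year
        else:
            intervals.append((start, prev))
            start = prev = year
    intervals.append((start, prev))
    return HPDResult(level=level, intervals=tuple(intervals), coverage=coverage)


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    levels: Sequence[float] = DEFAULT_HPD_LEVELS,
    max_sigma_away: float = 10.0,
) -> CalibratedDensity:
    """Calibrate one date on a 1-year calendar grid spanning the curve.

    Raises ``ValueError`` when the likelihood places essentially no mass on
    the curve support (every grid year further than ``max_sigma_away``
    standard deviations from the measurement).
    """
    if date.sigma_meas <= 0:
        raise ValueError("calibration requires sigma_meas > 0")
    grid = np.arange(int(np.ceil(curve.cal_min)), int(np.floor(curve.cal_max)) + 1)
    mu = curve.mu_at(grid)
    sigma_curve = curve.sigma_at(grid)
    sigma_tot = np.sqrt(
        date.sigma_meas ** 2 + date.sigma_delta_r ** 2 + sigma_curve ** 2
    )
    z = (date.measured_age - (mu + date.delta_r)) / sigma_tot
    if np.min(np.abs(z)) > max_sigma_away:
        raise ValueError(
            f"date {date.label or date.measured_age!r}: no overlap between the "
            "measurement and the calibration curve support"
        )
    loglik = -0.5 * z ** 2 - np.log(sigma_tot)
    loglik -= loglik.max()
    mass = np.exp(loglik)
    mass /= mass.sum()

    hpds = {float(level): hpd(grid, mass, float(level)) for level in levels}
    return CalibratedDensity(cal_bp=grid, mass=mass, hpd=hpds, label=date.label)


def calibrate_table(
    dates: pd.DataFrame,
    curve: CalibrationCurve,
    levels: Sequence[float] = DEFAULT_HPD_LEVELS,
) -> dict[str, CalibratedDensity]:
    """Calibrate every row of a dates table; keyed by specimen label."""
    out: dict[str, CalibratedDensity] = {}
    for row in dates.itertuples(index=False):
        date = RadiocarbonDate(
            measured_age=float(row.c14_age),
            sigma_meas=float(row.sigma),
            delta_r=float(row.delta_r),
            sigma_delta_r=float(row.sigma_delta_r),
            label=str(row.specimen),
        )
        out[date.label] = calibrate_date(date, curve, levels=levels)
    return out


def round_interval(interval: tuple[int, int], multiple: int) -> tuple[int, int]:
    """Round interval endpoints outward-neutrally to a reporting multiple.

    Mirrors the common convention of presenting calibrated ranges rounded
    to (say) 10 years; the underlying densities are never rounded.
    """
    lo, hi = interval
    r = int(multiple)
    return (int(round(lo / r) * r), int(round(hi / r) * r))
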