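"""End-to-end orchestration: damage -> genotype -> assign -> calibrate.

Every stage is a pure function of (inputs, config, seed); repeated runs
with the same inputs produce byte-identical outputs.  Stage failures are
recorded per specimen and do not abort the remaining stages — a report row
is emitted for every specimen seen in the observations or dates, even if
every stage no-calls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as itio
from .assign import (AssignConfig, CohortSummary, EcotypeAssignment, UNASSIGNED,
                     assign_ecotype, assignments_to_frame, classify_cohort)
from .calibrate import (DEFAULT_HPD_LEVELS, CalibratedDensity, RadiocarbonDate,
                        SKREI_DELTA_R, STATIONARY_DELTA_R, calibrate_date,
                        read_curve, round_interval, write_curve)
from .damage import (AuthenticityCall, DamageParams, authenticity_check,
                     fit_decay, profile_damage)
from .genotype import (GenotypeConfig, InversionGenotypeCall, calls_to_frame,
                       genotype_all)
from .synth import (DEFAULT_POPULATIONS, SimulationConfig, make_panel,
                    make_wiggly_curve, simulate_cohort, simulate_radiocarbon,
                    strong_differentiation_frequencies)

log = logging.getLogger("invertype")


@dataclass
class RunConfig:
    """Paths and per-stage settings for a pipeline run."""

    panel: Optional[Path] = None
    freqs: Optional[Path] = None
    obs: Optional[Path] = None
    dates: Optional[Path] = None
    curve: Optional[Path] = None
    out_dir: Path = Path("invertype_out")
    seed: int = 0
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_specimens: int = 20
    sites_per_inversion: int = 100
    levels: tuple[float, ...] = DEFAULT_HPD_LEVELS
    round_to: Optional[int] = None
    min_d0: float = 0.05


@dataclass
class SpecimenReport:
    specimen: str
    authenticity: Optional[AuthenticityCall]
    damage: Optional[DamageParams]
    calls: list[InversionGenotypeCall]
    assignment: Optional[EcotypeAssignment]
    calibration: Optional[CalibratedDensity]
    errors: list[str] = field(default_factory=list)

    def to_dict(self, round_to: Optional[int] = None) -> dict:
        d: dict = {"specimen": self.specimen}
        if self.damage is not None:
            d["damage"] = {
                "d0_hat": self.damage.d0_hat,
                "lambda_hat": self.damage.lambda_hat,
                "authentic_like": self.authenticity.authentic_like,
                "rationale": self.authenticity.rationale,
            }
        d["inversions"] = {
            c.inversion_id: {
                "posterior": dict(zip(("AA", "AB", "BB"), c.posterior)),
                "hard_call": c.hard_call,
                "n_sites_used": c.n_sites_used,
                "n_reads_used": c.n_reads_used,
            }
            for c in self.calls
        }
        if self.assignment is not None:
            d["assignment"] = {
                "posterior": self.assignment.posterior,
                "label": self.assignment.label,
                "n_inversions_used": self.assignment.n_inversions_used,
            }
        if self.calibration is not None:
            d["calibration"] = {
                "mode_cal_bp": self.calibration.mode,
                "hpd": {
                    f"{level:g}": {
                        "intervals": [
                            list(round_interval(iv, round_to) if round_to else iv)
                            for iv in res.intervals
                        ],
                        "coverage": res.coverage,
                    }
                    for level, res in sorted(self.calibration.hpd.items())
                },
            }
        if self.errors:
            d["errors"] = list(self.errors)
        return d


def run_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Write a complete synthetic fixture set under ``cfg.out_dir``.

    Produces panel, frequency table, per-specimen truth, read observations,
    radiocarbon dates (with ecotype-specific reservoir offsets keyed to the
    true population) and a synthetic calibration curve.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)

    panel = make_panel(cfg.sites_per_inversion, seed=cfg.seed)
    freqs = strong_differentiation_frequencies()
    curve = make_wiggly_curve()

    # cohort-level draws (population labels, true ages, measurements) use a
    # dedicated substream so they never perturb per-specimen read streams
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2 ** 20,)))
    populations = list(dict.fromkeys(freqs["population"]))
    names = [f"SIM{i:04d}" for i in range(cfg.n_specimens)]
    assigned = [populations[rng.integers(len(populations))] for _ in names]
    ages = rng.uniform(2100.0, 4300.0, size=cfg.n_specimens)

    truth, obs = simulate_cohort(
        list(zip(names, assigned)), panel, freqs, sim, true_cal_ages=ages
    )

    date_rows = []
    for name, pop, age in zip(names, assigned, ages):
        dr, sdr = SKREI_DELTA_R if pop == "NEAC" else STATIONARY_DELTA_R
        date = simulate_radiocarbon(
            float(age), curve, sigma_meas=30.0, delta_r=dr, sigma_delta_r=sdr,
            rng=rng, label=name,
        )
        date_rows.append((name, date.measured_age, date.sigma_meas,
                          date.delta_r, date.sigma_delta_r))
    dates = pd.DataFrame(date_rows, columns=itio.DATES_COLUMNS)

    paths = {
        "panel": out / "panel.tsv",
        "freqs": out / "frequencies.tsv",
        "truth": out / "truth.tsv",
        "obs": out / "observations.tsv",
        "dates": out / "dates.tsv",
        "curve": out / "curve.14c",
    }
    itio.write_table(panel, paths["panel"])
    itio.write_table(freqs, paths["freqs"])
    itio.write_table(truth, paths["truth"])
    itio.write_table(obs, paths["obs"])
    itio.write_table(dates, paths["dates"])
    write_curve(curve, paths["curve"], comment="synthetic wiggly curve")
    log.info("simulate: wrote %d specimens, %d observations to %s",
             cfg.n_specimens, len(obs), out)
    return paths


def run_all(cfg: RunConfig) -> tuple[list[SpecimenReport], Optional[CohortSummary], list[str]]:
    """Execute damage -> genotype -> assign -> calibrate over all inputs.

    Returns per-specimen reports, the cohort summary (None when nothing was
    assignable) and a flat list of stage-error strings.  Writes machine- and
    human-readable reports under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_errors: list[str] = []

    panel = itio.read_panel(cfg.panel)
    freqs = itio.read_frequencies(cfg.freqs)
    obs = itio.read_observations(cfg.obs)
    dates = itio.read_dates(cfg.dates) if cfg.dates else None

    curve = None
    if dates is not None:
        if cfg.curve is None:
            stage_errors.append("calibrate: dates provided without a curve file")
            log.error("calibrate: dates provided without a curve file")
        else:
            try:
                curve = read_curve(cfg.curve)
            except (OSError, ValueError) as exc:
                stage_errors.append(f"calibrate: cannot load curve: {exc}")
                log.error("calibrate: cannot load curve: %s", exc)

    specimens = sorted(
        set(map(str, obs["specimen"].unique() if len(obs) else []))
        | set(map(str, dates["specimen"].unique() if dates is not None else []))
    )
    log.info("run-all: %d specimens, %d observations in", len(specimens), len(obs))

    # --- damage stage -----------------------------------------------------
    damage_by_specimen: dict[str, DamageParams] = {}
    auth_by_specimen: dict[str, AuthenticityCall] = {}
    errors_by_specimen: dict[str, list[str]] = {s: [] for s in specimens}
    for s in specimens:
        s_obs = obs[obs["specimen"] == s]
        if len(s_obs) == 0:
            errors_by_specimen[s].append("damage: no observations")
            continue
        try:
            prof = profile_damage(s_obs, panel)
            params = fit_decay(prof)
            damage_by_specimen[s] = params
            auth_by_specimen[s] = authenticity_check(params, min_d0=cfg.min_d0)
        except ValueError as exc:
            msg = f"damage: {exc}"
            errors_by_specimen[s].append(msg)
            log.warning("damage [%s]: %s", s, exc)
    log.info("damage: %d/%d specimens profiled", len(damage_by_specimen),
             len(specimens))

    # --- genotype stage ---------------------------------------------------
    calls = genotype_all(obs, panel, cfg.genotype,
                         damage=damage_by_specimen or None, specimens=specimens)
    calls_by_specimen: dict[str, list[InversionGenotypeCall]] = {s: [] for s in specimens}
    for c in calls:
        calls_by_specimen[c.specimen].append(c)
    n_called = sum(1 for c in calls if c.hard_call != "no-call")
    log.info("genotype: %d calls (%d hard, %d no-call)", len(calls), n_called,
             len(calls) - n_called)

    # --- assign stage -----------------------------------------------------
    assignments: dict[str, EcotypeAssignment] = {}
    for s in specimens:
        try:
            assignments[s] = assign_ecotype(calls_by_specimen[s], freqs, cfg.assign)
        except (KeyError, ValueError) as exc:
            errors_by_specimen[s].append(f"assign: {exc}")
            log.warning("assign [%s]: %s", s, exc)

    # --- calibrate stage --------------------------------------------------
    calibrations: dict[str, CalibratedDensity] = {}
    if dates is not None and curve is not None:
        for row in dates.itertuples(index=False):
            s = str(row.specimen)
            try:
                date = RadiocarbonDate(
                    measured_age=float(row.c14_age), sigma_meas=float(row.sigma),
                    delta_r=float(row.delta_r),
                    sigma_delta_r=float(row.sigma_delta_r), label=s,
                )
                calibrations[s] = calibrate_date(date, curve, levels=cfg.levels)
            except ValueError as exc:
                errors_by_specimen.setdefault(s, []).append(f"calibrate: {exc}")
                log.warning("calibrate [%s]: %s", s, exc)
        log.info("calibrate: %d/%d dates calibrated", len(calibrations), len(dates))

    reports = [
        SpecimenReport(
            specimen=s,
            authenticity=auth_by_specimen.get(s),
            damage=damage_by_specimen.get(s),
            calls=calls_by_specimen[s],
            assignment=assignments.get(s),
            calibration=calibrations.get(s),
            errors=errors_by_specimen.get(s, []),
        )
        for s in specimens
    ]
    stage_errors.extend(
        f"{s}: {e}" for s in specimens for e in errors_by_specimen.get(s, [])
    )

    summary = classify_cohort(list(assignments.values())) if assignments else None

    _write_outputs(cfg, out, reports, summary, calls, list(assignments.values()),
                   calibrations)
    return reports, summary, stage_errors


def _write_outputs(cfg, out: Path, reports, summary, calls, assignments,
                   calibrations) -> None:
    itio.write_table(calls_to_frame(calls), out / "calls.tsv")
    if assignments:
        itio.write_table(assignments_to_frame(assignments), out / "assignments.tsv")
    dmg_rows = [
        (r.specimen, r.damage.d0_hat, r.damage.lambda_hat, r.damage.residual,
         r.authenticity.authentic_like)
        for r in reports if r.damage is not None
    ]
    if dmg_rows:
        itio.write_table(
            pd.DataFrame(dmg_rows, columns=["specimen", "d0_hat", "lambda_hat",
                                            "residual", "authentic_like"]),
            out / "damage.tsv",
        )
    for s, dens in calibrations.items():
        itio.write_table(dens.to_frame(), out / "calibration" / f"{s}.tsv")

    report_json = {
        "specimens": [r.to_dict(cfg.round_to) for r in reports],
    }
    if summary is not None:
        report_json["cohort"] = {
            "counts": summary.counts, "fractions": summary.fractions,
            "n": summary.n,
        }
    (out / "report.json").write_text(json.dumps(report_json, indent=2,
                                                sort_keys=True) + "\n")
    (out / "report.txt").write_text(_text_report(reports, summary))


def _text_report(reports: Sequence[SpecimenReport],
                 summary: Optional[CohortSummary]) -> str:
    lines = []
    for r in reports:
        lines.append(f"specimen {r.specimen}")
        if r.damage is not None:
            mark = "authentic-like" if r.authenticity.authentic_like else "NOT authentic-like"
            lines.append(
                f"  damage: d0={r.damage.d0_hat:.3f} lambda={r.damage.lambda_hat:.3f} [{mark}]"
            )
        for c in r.calls:
            lines.append(
                f"  {c.inversion_id}: {c.hard_call} "
                f"(AA={c.posterior[0]:.3f} AB={c.posterior[1]:.3f} "
                f"BB={c.posterior[2]:.3f}; {c.n_sites_used} sites, "
                f"{c.n_reads_used} reads)"
            )
        if r.assignment is not None:
            post = " ".join(f"{p}={v:.4f}" for p, v in r.assignment.posterior.items())
            lines.append(f"  assignment: {r.assignment.label} ({post})")
        if r.calibration is not None:
            for level, res in sorted(r.calibration.hpd.items()):
                ivs = ", ".join(f"{lo}-{hi}" for lo, hi in res.intervals)
                lines.append(f"  cal {level * 100:.1f}%: {ivs} cal BP")
        for e in r.errors:
            lines.append(f"  ! {e}")
    if summary is not None:
        lines.append("cohort: " + " ".join(
            f"{lab}={cnt}" for lab, cnt in summary.counts.items()))
    return "\n".join(lines) + "\n"
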