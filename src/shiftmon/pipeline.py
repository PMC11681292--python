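"""End-to-end monitoring pipeline over a scored-cases table.

The four stages, run in order:

1. **Profile** — per-period case counts, incidence and score summaries, with
   a flag for periods whose incidence deviates grossly from the pooled rate
   (a tell-tale of labelling-policy changes).
2. **Discrimination** — per-period AUROC/AUPRC with Hanley–McNeil SEs and
   all-pairs Z-tests for stability.
3. **Calibration** — Platt scaling fitted on the reserved calibration split,
   per-period reliability curves and ECE/MCE before/after recalibration,
   and a calibration-shift flag per period.
4. **Decision impact** — operating threshold balancing over- and
   underdiagnosis (chosen on the calibration split, calibrated scores),
   per-period confusion summaries and decision curves, then pairwise
   bootstrap comparison of decision curves after standardising incidence
   across periods.

Everything is deterministic given the config seed, and the report
round-trips losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import apply_platt, calibration_shift_report, fit_platt
from .decision import (
    DEFAULT_THRESHOLDS_OF_INTEREST,
    compare_decision_curves,
    confusion_summary,
    decision_curve,
    select_threshold,
    standardize_incidence,
)
from .discrimination import metrics_table, pairwise_auroc_tests, roc_summary
from .exceptions import DegenerateDataError, PipelineError
from .io import CALIBRATION, TEST, read_cases
from .synthetic import ScoredCohort

logger = logging.getLogger("shiftmon")

__all__ = ["MonitoringConfig", "MonitoringReport", "profile_periods", "run_monitoring"]


@dataclasses.dataclass(frozen=True)
class MonitoringConfig:
    """Configuration of one monitoring run.

    When the input has no populated ``split`` column, ``calib_fraction`` of
    cases (default 10%, the reserved validation/calibration/threshold
    split) is drawn uniformly at random using ``seed``.
    """

    input: str | None = None
    calib_fraction: float = 0.10
    n_bins: int = 10
    shift_margin: float = 0.05
    profile_margin: float = 0.50
    thresholds_of_interest: Sequence[float] = DEFAULT_THRESHOLDS_OF_INTEREST
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "thresholds_of_interest", tuple(float(t) for t in self.thresholds_of_interest)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds_of_interest"] = list(self.thresholds_of_interest)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonitoringConfig":
        return cls(**dict(d))


def profile_periods(frame: pd.DataFrame, rel_margin: float = 0.50) -> pd.DataFrame:
    """Per-period cohort profile: n, incidence and raw-score summary.

    A period is flagged when its incidence differs from the pooled incidence
    by more than ``rel_margin`` relatively — the pattern seen when early
    years are systematically under-labelled.
    """
    if frame.empty:
        raise DegenerateDataError("empty input")
    pooled = frame["label"].mean()
    rows = []
    for period in dict.fromkeys(frame["period"]):
        sub = frame[frame["period"] == period]
        inc = sub["label"].mean()
        rows.append(
            {
                "period": period,
                "n": len(sub),
                "n_pos": int(sub["label"].sum()),
                "incidence": float(inc),
                "score_min": float(sub["raw_score"].min()),
                "score_median": float(sub["raw_score"].median()),
                "score_max": float(sub["raw_score"].max()),
                "incidence_flag": bool(pooled > 0 and abs(inc - pooled) / pooled > rel_margin),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class MonitoringReport:
    """Machine-readable result of one monitoring run; every section covers
    every period of the input."""

    profile: list[dict]
    discrimination: list[dict]
    auroc_tests: list[dict]
    platt: dict
    calibration_reference: dict
    calibration: list[dict]
    threshold: float
    confusion: list[dict]
    decision_curves: list[dict]
    dca_comparisons: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonitoringReport":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})

    @classmethod
    def from_json(cls, text: str) -> "MonitoringReport":
        return cls.from_dict(json.loads(text))


def _assign_split(frame: pd.DataFrame, calib_fraction: float, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = len(frame)
    n_cal = int(round(calib_fraction * n))
    idx = rng.choice(n, size=n_cal, replace=False)
    split = np.full(n, TEST, dtype=object)
    split[idx] = CALIBRATION
    frame = frame.copy()
    frame["split"] = split
    return frame


def _stage(name: str):
    """Decorator-free stage wrapper: run fn, log size/elapsed, rewrap errors."""

    class _Ctx:
        def __init__(self):
            self.t0 = None

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                logger.info("stage %s done in %.2fs", name, time.perf_counter() - self.t0)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


def run_monitoring(
    config: MonitoringConfig, cohort: ScoredCohort | None = None
) -> MonitoringReport:
    """Execute the full monitoring pipeline and return the report.

    ``cohort`` may be passed directly; otherwise it is loaded from
    ``config.input``.  When ``config.out_dir`` is set, all CSV side-tables
    and ``report.json`` are written there — only after every stage has
    succeeded, so a failed run leaves no partial outputs.
    """
    with _stage("load"):
        if cohort is None:
            if config.input is None:
                raise DegenerateDataError("no cohort given and config.input is unset")
            frame = read_cases(config.input)
            if not set(frame["split"].unique()) <= {CALIBRATION, TEST} or (
                frame["split"] == ""
            ).any():
                frame = _assign_split(frame, config.calib_fraction, config.seed)
            cohort = ScoredCohort(frame)
        logger.info("loaded %d cases, %d periods", cohort.n, len(cohort.periods))

    with _stage("profile"):
        profile = profile_periods(cohort.frame, rel_margin=config.profile_margin)

    with _stage("platt_fit"):
        cal = cohort.calibration()
        if cal["label"].nunique() < 2:
            raise DegenerateDataError("calibration split lacks one outcome class")
        platt = fit_platt(cal["raw_score"].to_numpy(), cal["label"].to_numpy())

    with _stage("threshold_selection"):
        cal_probs = apply_platt(platt, cal["raw_score"].to_numpy())
        threshold = select_threshold(cal_probs, cal["label"].to_numpy())

    with _stage("discrimination"):
        summaries = [
            roc_summary(split["raw_score"].to_numpy(), split["label"].to_numpy(), period=p)
            for p, split in cohort.test_splits().items()
        ]
        tests = pairwise_auroc_tests(summaries)

    with _stage("calibration"):
        cal_report = calibration_shift_report(
            cohort, platt=platt, n_bins=config.n_bins, margin=config.shift_margin
        )

    with _stage("decision"):
        confusion = []
        curves = []
        for period, split in cohort.test_splits().items():
            probs = apply_platt(platt, split["raw_score"].to_numpy())
            labels = split["label"].to_numpy()
            confusion.append(
                {"period": period, **confusion_summary(probs, labels, threshold).to_dict()}
            )
            curve = decision_curve(probs, labels, period=period)
            curves.append(
                {
                    "period": period,
                    "thresholds": curve.thresholds.tolist(),
                    "nb_model": curve.nb_model.tolist(),
                    "nb_all": curve.nb_all.tolist(),
                    "nb_none": curve.nb_none.tolist(),
                }
            )

    with _stage("dca_comparison"):
        seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
        standardized = standardize_incidence(cohort, seed=int(seeds[0]))
        comparisons = []
        periods = standardized.periods
        comp_seed = int(seeds[1])
        for i, pa in enumerate(periods):
            for pb in periods[i + 1 :]:
                sa = standardized.test(pa)
                sb = standardized.test(pb)
                comp = compare_decision_curves(
                    apply_platt(platt, sa["raw_score"].to_numpy()),
                    sa["label"].to_numpy(),
                    apply_platt(platt, sb["raw_score"].to_numpy()),
                    sb["label"].to_numpy(),
                    thresholds=config.thresholds_of_interest,
                    n_boot=config.n_boot,
                    seed=comp_seed,
                    period_a=pa,
                    period_b=pb,
                )
                comp_seed += 1
                comparisons.append(comp)

    with _stage("report"):
        calibration_entries = []
        for period, entry in cal_report.periods.items():
            calibration_entries.append(
                {
                    "period": period,
                    "raw": {
                        "curve": entry.raw_curve.to_frame().to_dict(orient="list"),
                        **entry.raw_errors.to_dict(),
                    },
                    "calibrated": {
                        "curve": entry.calibrated_curve.to_frame().to_dict(orient="list"),
                        **entry.calibrated_errors.to_dict(),
                    },
                    "shift_flag": entry.shift_flag,
                }
            )
        config_dict = config.to_dict()
        report = MonitoringReport(
            profile=profile.to_dict(orient="records"),
            discrimination=[s.to_dict() for s in summaries],
            auroc_tests=[t.to_dict() for t in tests],
            platt=platt.to_dict(),
            calibration_reference={
                "raw": cal_report.reference_raw.to_dict(),
                "calibrated": cal_report.reference_calibrated.to_dict(),
                "margin": cal_report.margin,
                "n_bins": cal_report.n_bins,
            },
            calibration=calibration_entries,
            threshold=float(threshold),
            confusion=confusion,
            decision_curves=curves,
            dca_comparisons=[c.to_dict() for c in comparisons],
            provenance={
                "tool": "shiftmon",
                "version": __version__,
                "seed": config.seed,
                "config_hash": hashlib.sha256(
                    json.dumps(config_dict, sort_keys=True).encode()
                ).hexdigest(),
                "config": config_dict,
            },
        )

    if config.out_dir is not None:
        with _stage("write_outputs"):
            _write_outputs(
                Path(config.out_dir), report, profile, summaries, tests, cal_report, comparisons
            )
    return report


def _write_outputs(out_dir, report, profile, summaries, tests, cal_report, comparisons):
    out_dir.mkdir(parents=True, exist_ok=True)
    profile.to_csv(out_dir / "profile.csv", index=False)
    metrics_table(summaries).to_csv(out_dir / "metrics.csv", index=False)
    pd.DataFrame([t.to_dict() for t in tests]).to_csv(out_dir / "auroc_tests.csv", index=False)
    cal_report.curves_table().to_csv(out_dir / "calibration_curves.csv", index=False)
    cal_report.errors_table().to_csv(out_dir / "calibration_errors.csv", index=False)
    pd.DataFrame(report.confusion).to_csv(out_dir / "confusion.csv", index=False)
    curve_rows = []
    for entry in report.decision_curves:
        curve_rows.append(
            pd.DataFrame(
                {
                    "period": entry["period"],
                    "threshold": entry["thresholds"],
                    "nb_model": entry["nb_model"],
                    "nb_all": entry["nb_all"],
                    "nb_none": entry["nb_none"],
                }
            )
        )
    pd.concat(curve_rows, ignore_index=True).to_csv(out_dir / "decision_curves.csv", index=False)
    pd.concat([c.to_frame() for c in comparisons], ignore_index=True).to_csv(
        out_dir / "dca_comparisons.csv", index=False
    )
    (out_dir / "report.json").write_text(report.to_json())
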