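"""Recalibration and calibration-shift detection.

A deployed risk model can keep its discrimination while its probabilities
drift away from observed event rates — the classic failure mode that AUROC
monitoring cannot see.  This module provides:

* Platt scaling fitted by maximum likelihood on the reserved calibration
  split, in the original parameterisation ``p = 1 / (1 + exp(A f + B))``
  with ``f = logit(raw_score)`` — ``(A, B) = (-1, 0)`` is the identity;
* quantile-binned reliability curves (equal case counts per bin) with
  Wilson 95% intervals on the observed rate;
* expected / maximum calibration error (ECE / MCE) on the same bins;
* a per-period shift report: a period is flagged when its post-calibration
  ECE exceeds the calibration split's post-calibration ECE by more than a
  configurable absolute margin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConvergenceError, DegenerateDataError
from .synthetic import ScoredCohort

__all__ = [
    "PlattModel",
    "ReliabilityCurve",
    "CalibrationErrors",
    "fit_platt",
    "apply_platt",
    "reliability_curve",
    "calibration_errors",
    "calibration_shift_report",
    "PeriodCalibration",
    "CalibrationShiftReport",
]

_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class PlattModel:
    """Logistic recalibration map ``p = 1 / (1 + exp(slope * f + offset))``
    on ``f = logit(raw_score)``; strictly increasing in the raw score
    whenever ``slope < 0``."""

    slope: float
    offset: float
    n_fit: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_platt(
    raw_scores,
    labels,
    *,
    smoothing: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PlattModel:
    """Maximum-likelihood Platt fit by Newton iterations.

    Parameters
    ----------
    smoothing
        When True, replace the 0/1 targets with the Bayes-adjusted targets
        (n_pos + 1)/(n_pos + 2) and 1/(n_neg + 2).  Off by default.
    tol
        Convergence when the max-norm of the log-likelihood gradient falls
        below this value.
    """
    f = np.asarray(raw_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if f.size < 20:
        raise DegenerateDataError("Platt fit needs at least 20 cases")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("Platt fit needs both outcome classes")
    if smoothing:
        y = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    f = logit(np.clip(f, _EPS, 1.0 - _EPS))

    a, b = -1.0, 0.0  # identity start
    for _ in range(max_iter):
        p = expit(-(a * f + b))
        r = p - y
        g = np.array([-(r * f).sum(), -r.sum()])
        if np.abs(g).max() < tol:
            return PlattModel(slope=a, offset=b, n_fit=f.size)
        w = p * (1.0 - p)
        h = np.array([[(w * f * f).sum(), (w * f).sum()], [(w * f).sum(), w.sum()]])
        h[np.diag_indices_from(h)] += 1e-12
        step = np.linalg.solve(h, g)
        a -= step[0]
        b -= step[1]
    raise ConvergenceError(f"Platt fit did not converge in {max_iter} Newton steps")


def apply_platt(model: PlattModel, raw_scores) -> np.ndarray:
    """Map raw scores through the fitted recalibration curve (elementwise)."""
    f = logit(np.clip(np.asarray(raw_scores, dtype=float), _EPS, 1.0 - _EPS))
    return expit(-(model.slope * f + model.offset))


@dataclasses.dataclass(frozen=True)
class ReliabilityCurve:
    """Quantile-binned predicted-vs-observed curve; bin sizes differ by at
    most one and every case lands in exactly one bin."""

    mean_pred: np.ndarray
    observed: np.ndarray
    n_bin: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    period: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.n_bin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "mean_pred": self.mean_pred,
                "observed": self.observed,
                "n": self.n_bin,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _quantile_bins(probs: np.ndarray, n_bins: int) -> list[np.ndarray]:
    # stable sort on (prob, position) so tied probabilities split
    # deterministically across bin boundaries
    order = np.lexsort((np.arange(probs.size), probs))
    return np.array_split(order, n_bins)


def reliability_curve(probs, labels, n_bins: int = 10, period: str = "") -> ReliabilityCurve:
    """Sort cases by predicted probability, cut into ``n_bins`` contiguous
    equal-count groups, and report per-bin mean prediction, observed event
    rate, and a Wilson 95% CI on the observed rate."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size < n_bins:
        raise DegenerateDataError(f"need at least n_bins={n_bins} cases, got {probs.size}")
    if n_bins < 1:
        raise DegenerateDataError("n_bins must be >= 1")
    groups = _quantile_bins(probs, n_bins)
    n_bin = np.array([g.size for g in groups])
    mean_pred = np.array([probs[g].mean() for g in groups])
    events = np.array([labels[g].sum() for g in groups])
    observed = events / n_bin
    ci_low, ci_high = proportion_confint(events, n_bin, alpha=0.05, method="wilson")
    return ReliabilityCurve(
        mean_pred=mean_pred,
        observed=observed,
        n_bin=n_bin,
        ci_low=np.asarray(ci_low, dtype=float),
        ci_high=np.asarray(ci_high, dtype=float),
        period=str(period),
    )


@dataclasses.dataclass(frozen=True)
class CalibrationErrors:
    """ECE (count-weighted mean absolute per-bin gap) and MCE (maximum gap);
    ECE <= MCE always."""

    ece: float
    mce: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def errors_from_curve(curve: ReliabilityCurve) -> CalibrationErrors:
    gaps = np.abs(curve.mean_pred - curve.observed)
    weights = curve.n_bin / curve.n_bin.sum()
    return CalibrationErrors(ece=float(np.sum(weights * gaps)), mce=float(gaps.max()))


def calibration_errors(probs, labels, n_bins: int = 10) -> CalibrationErrors:
    """ECE and MCE on the same quantile binning as the reliability curve."""
    return errors_from_curve(reliability_curve(probs, labels, n_bins=n_bins))


@dataclasses.dataclass
class PeriodCalibration:
    """Reliability curves and errors for one period, before and after
    recalibration, plus the shift flag."""

    period: str
    raw_curve: ReliabilityCurve
    calibrated_curve: ReliabilityCurve
    raw_errors: CalibrationErrors
    calibrated_errors: CalibrationErrors
    shift_flag: bool


@dataclasses.dataclass
class CalibrationShiftReport:
    """Per-period calibration report anchored to the calibration split.

    ``reference_calibrated.ece`` is the benchmark: a period is flagged when
    its post-calibration ECE exceeds it by more than ``margin``.
    """

    reference_raw: CalibrationErrors
    reference_calibrated: CalibrationErrors
    margin: float
    n_bins: int
    periods: dict[str, PeriodCalibration]

    def flagged_periods(self) -> list[str]:
        return [p for p, entry in self.periods.items() if entry.shift_flag]

    def curves_table(self) -> pd.DataFrame:
        rows = []
        for period, entry in self.periods.items():
            for phase, curve in (("raw", entry.raw_curve), ("calibrated", entry.calibrated_curve)):
                frame = curve.to_frame()
                frame.insert(0, "phase", phase)
                frame.insert(0, "period", period)
                rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def errors_table(self) -> pd.DataFrame:
        rows = []
        for period, entry in self.periods.items():
            rows.append({"period": period, "phase": "raw", **entry.raw_errors.to_dict()})
            rows.append(
                {"period": period, "phase": "calibrated", **entry.calibrated_errors.to_dict()}
            )
        return pd.DataFrame(rows)


def calibration_shift_report(
    cohort: ScoredCohort,
    platt: PlattModel | None = None,
    n_bins: int = 10,
    margin: float = 0.05,
) -> CalibrationShiftReport:
    """Build the per-period calibration-shift report.

    The Platt model is fitted on the cohort's calibration split when not
    supplied.  For every period the report holds reliability curves and
    ECE/MCE on raw and on recalibrated scores; the flag fires when the
    period's post-calibration ECE exceeds the calibration split's
    post-calibration ECE by more than ``margin`` (absolute).
    """
    cal = cohort.calibration()
    if platt is None:
        platt = fit_platt(cal["raw_score"].to_numpy(), cal["label"].to_numpy())
    cal_raw = cal["raw_score"].to_numpy()
    cal_labels = cal["label"].to_numpy()
    reference_raw = calibration_errors(cal_raw, cal_labels, n_bins=n_bins)
    reference_cal = calibration_errors(apply_platt(platt, cal_raw), cal_labels, n_bins=n_bins)

    periods: dict[str, PeriodCalibration] = {}
    for period in cohort.periods:
        split = cohort.test(period)
        raw = split["raw_score"].to_numpy()
        labels = split["label"].to_numpy()
        calibrated = apply_platt(platt, raw)
        raw_curve = reliability_curve(raw, labels, n_bins=n_bins, period=period)
        cal_curve = reliability_curve(calibrated, labels, n_bins=n_bins, period=period)
        raw_err = errors_from_curve(raw_curve)
        cal_err = errors_from_curve(cal_curve)
        periods[period] = PeriodCalibration(
            period=period,
            raw_curve=raw_curve,
            calibrated_curve=cal_curve,
            raw_errors=raw_err,
            calibrated_errors=cal_err,
            shift_flag=bool(cal_err.ece > reference_cal.ece + margin),
        )
    return CalibrationShiftReport(
        reference_raw=reference_raw,
        reference_calibrated=reference_cal,
        margin=margin,
        n_bins=n_bins,
        periods=periods,
    )
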