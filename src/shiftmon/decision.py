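"""Decision impact of a risk model: alerts, thresholds, and net benefit.

The operating threshold is chosen on the reserved calibration split (after
recalibration) as the candidate that balances overdiagnosis (false-positive
rate) against underdiagnosis (false-negative rate).  Clinical utility over a
range of threshold probabilities is evaluated with decision-curve analysis:

    net benefit = TP/N - (FP/N) * p_t / (1 - p_t)

against the treat-all and treat-none reference strategies, and decision
curves from two periods are compared with an unpaired case-level bootstrap.
Because a curve's starting point (p_t = 0) equals the period's prevalence,
cross-period comparisons first standardise incidence by duplicating positive
cases in lower-incidence periods up to the maximum period incidence.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InvalidTargetError
from .synthetic import ScoredCohort, _split_groups

__all__ = [
    "DEFAULT_THRESHOLDS_OF_INTEREST",
    "AlertCategory",
    "ConfusionSummary",
    "DecisionCurve",
    "NbComparison",
    "select_threshold",
    "classify_alert",
    "confusion_summary",
    "net_benefit",
    "decision_curve",
    "standardize_incidence",
    "compare_decision_curves",
]

#: Default thresholds at which decision curves are statistically compared;
#: the low range is where alerting decisions for acute inpatient conditions
#: actually operate.
DEFAULT_THRESHOLDS_OF_INTEREST = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20)

#: Alert outcome categories.  ``TP_AFTER_ONSET`` ("arguably FN/TP") marks an
#: alert on a true case that was not strictly before onset — diagnostic
#: rather than predictive.  For rate computation it collapses into TP.
AlertCategory = ("TN", "FP", "FN", "TP", "TP_AFTER_ONSET")


def _counts_at(probs_sorted_pos, probs_sorted_neg, thresholds):
    """Vectorised (tp, fp) at each threshold; alert iff prob >= threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    n_pos = probs_sorted_pos.size
    n_neg = probs_sorted_neg.size
    tp = n_pos - np.searchsorted(probs_sorted_pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(probs_sorted_neg, thresholds, side="left")
    return tp, fp


def select_threshold(probs, labels) -> float:
    """Threshold minimising |FNR - FPR| over all candidate thresholds (the
    distinct predicted probabilities plus 0 and 1); ties broken by the
    smallest candidate.

    The objective is piecewise constant between observed probabilities, so
    this candidate grid is lossless.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("threshold selection needs both outcome classes")
    candidates = np.unique(np.concatenate([probs, [0.0, 1.0]]))
    pos = np.sort(probs[labels == 1])
    neg = np.sort(probs[labels == 0])
    tp, fp = _counts_at(pos, neg, candidates)
    fnr = (n_pos - tp) / n_pos
    fpr = fp / n_neg
    return float(candidates[np.argmin(np.abs(fnr - fpr))])  # argmin → first = smallest


def classify_alert(
    label: int,
    alerted: bool,
    onset_time: float | None = None,
    alert_time: float | None = None,
) -> str:
    """Assign one of the five alert-outcome categories.

    Controls: no alert → TN, alert → FP.  Cases: no alert → FN; alert before
    onset (or onset unknown) → TP; alert at or after onset → TP_AFTER_ONSET.
    """
    if label not in (0, 1):
        raise DegenerateDataError(f"label must be 0/1, got {label}")
    if label == 0:
        if onset_time is not None:
            raise DegenerateDataError("a control cannot have an onset time")
        return "FP" if alerted else "TN"
    if not alerted:
        return "FN"
    if onset_time is None:
        return "TP"
    if alert_time is None:
        raise DegenerateDataError("alerted case with known onset needs an alert time")
    return "TP" if alert_time < onset_time else "TP_AFTER_ONSET"


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Alert counts and rates at one operating threshold.  ``alert_rate`` is
    the fraction of cases alerted; FPR is overdiagnosis, FNR underdiagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def alert_rate(self) -> float:
        return (self.tp + self.fp) / self.n if self.n else 0.0

    @property
    def fpr(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else 0.0

    @property
    def fnr(self) -> float:
        denom = self.fn + self.tp
        return self.fn / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "threshold": self.threshold,
            "n": self.n,
            "alert_rate": self.alert_rate,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }


def confusion_summary(probs, labels, threshold: float) -> ConfusionSummary:
    """Counts and rates with the alert rule ``prob >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise InvalidTargetError(f"threshold must lie in [0, 1], got {threshold}")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise DegenerateDataError("empty input")
    alert = probs >= threshold
    return ConfusionSummary(
        tp=int(np.sum(alert & (labels == 1))),
        fp=int(np.sum(alert & (labels == 0))),
        fn=int(np.sum(~alert & (labels == 1))),
        tn=int(np.sum(~alert & (labels == 0))),
        threshold=float(threshold),
    )


def net_benefit(tp: float, fp: float, n: float, p_t: float) -> float:
    """NB = TP/N - (FP/N) * p_t/(1 - p_t), in units of true positives per
    patient."""
    if not 0.0 <= p_t < 1.0:
        raise InvalidTargetError(f"threshold probability must lie in [0, 1), got {p_t}")
    if n <= 0:
        raise DegenerateDataError("n must be positive")
    return tp / n - (fp / n) * (p_t / (1.0 - p_t))


@dataclasses.dataclass(frozen=True)
class DecisionCurve:
    """Net benefit of the model vs treat-all vs treat-none over a threshold
    grid.  Treat-none is identically zero; treat-all crosses zero exactly at
    the period's prevalence."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    period: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )


def decision_curve(probs, labels, thresholds=None, period: str = "") -> DecisionCurve:
    """Net benefit across a threshold grid (default 0.00–0.99 in steps of
    0.01)."""
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise InvalidTargetError("threshold grid is empty")
    if thresholds.min() < 0 or thresholds.max() >= 1:
        raise InvalidTargetError("threshold grid must lie within [0, 1)")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = probs.size
    if n == 0:
        raise DegenerateDataError("empty input")
    pos = np.sort(probs[labels == 1])
    neg = np.sort(probs[labels == 0])
    tp, fp = _counts_at(pos, neg, thresholds)
    weight = thresholds / (1.0 - thresholds)
    nb_model = tp / n - (fp / n) * weight
    pi = labels.mean()
    nb_all = pi - (1.0 - pi) * weight
    return DecisionCurve(
        thresholds=thresholds,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(thresholds),
        period=str(period),
    )


def _positives_to_add(n_pos: int, n: int, target: float) -> int:
    """Duplicate count k >= 0 minimising |(n_pos + k)/(n + k) - target|;
    ties broken toward the smaller k."""
    if target >= 1.0:
        raise InvalidTargetError("target incidence must be < 1")
    k0 = (target * n - n_pos) / (1.0 - target)
    candidates = sorted({max(int(np.floor(k0)), 0), max(int(np.ceil(k0)), 0)})
    return min(candidates, key=lambda k: (abs((n_pos + k) / (n + k) - target), k))


def standardize_incidence(cohort: ScoredCohort, seed: int) -> ScoredCohort:
    """Equalise incidence across the per-period test splits by duplicating
    positives (sampled with replacement) in every lower-incidence period up
    to the maximum period incidence.

    Existing rows are never modified; appended rows are verbatim copies of
    positive cases.  Decision curves of the augmented periods then all start
    (p_t = 0) at the common target incidence.
    """
    periods = cohort.periods
    if len(periods) < 2:
        raise DegenerateDataError("incidence standardisation needs at least 2 periods")
    incidences = {p: cohort.incidence(p) for p in periods}
    target = max(incidences.values())
    rng = np.random.default_rng(seed)
    extra_frames = []
    for period in periods:
        split = cohort.test(period)
        n = len(split)
        n_pos = int(split["label"].sum())
        if n_pos == 0:
            raise DegenerateDataError(f"period {period!r} has no positives to duplicate")
        k = _positives_to_add(n_pos, n, target)
        if k == 0:
            continue
        pos_index = split.index[split["label"] == 1].to_numpy()
        picked = rng.choice(pos_index, size=k, replace=True)
        extra_frames.append(cohort.frame.loc[picked])
    if not extra_frames:
        return ScoredCohort(cohort.frame.copy())
    frame = pd.concat([cohort.frame, *extra_frames], ignore_index=True)
    return ScoredCohort(frame)


@dataclasses.dataclass(frozen=True)
class NbComparison:
    """Unpaired bootstrap comparison of two periods' decision curves at the
    thresholds of interest.  No multiplicity correction is applied."""

    period_a: str
    period_b: str
    thresholds: tuple[float, ...]
    p_values: tuple[float, ...]
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "period_a": self.period_a,
            "period_b": self.period_b,
            "thresholds": list(self.thresholds),
            "p_values": list(self.p_values),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_a": self.period_a,
                "period_b": self.period_b,
                "threshold": list(self.thresholds),
                "p_value": list(self.p_values),
            }
        )


def _bootstrap_nb(probs, labels, thresholds, n_boot, rng, chunk=256):
    """Net benefit per bootstrap replicate (rows) and threshold (columns);
    cases resampled with replacement within the period."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = probs.size
    thresholds = np.asarray(thresholds, dtype=float)
    weight = thresholds / (1.0 - thresholds)
    tp_ind = ((probs[:, None] >= thresholds) & (labels[:, None] == 1)).astype(np.float64)
    fp_ind = ((probs[:, None] >= thresholds) & (labels[:, None] == 0)).astype(np.float64)
    out = np.empty((n_boot, thresholds.size))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        tp = tp_ind[idx].sum(axis=1)
        fp = fp_ind[idx].sum(axis=1)
        out[done : done + m] = tp / n - (fp / n) * weight
        done += m
    return out


def compare_decision_curves(
    probs_a,
    labels_a,
    probs_b,
    labels_b,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_OF_INTEREST,
    n_boot: int = 1000,
    seed: int = 0,
    period_a: str = "a",
    period_b: str = "b",
) -> NbComparison:
    """Unpaired bootstrap test of NB_a(p_t) = NB_b(p_t) at each threshold of
    interest.

    Cases are resampled with replacement within each period independently,
    ``n_boot`` times; at each threshold the two-sided p-value is
    ``2 * min(frac(dNB <= 0), frac(dNB >= 0))`` clipped to [0, 1], where
    ``dNB = NB_a - NB_b`` per replicate.
    """
    if n_boot < 100:
        raise DegenerateDataError(f"n_boot must be >= 100, got {n_boot}")
    for name, labels in (("a", labels_a), ("b", labels_b)):
        labels = np.asarray(labels)
        if labels.sum() == 0 or labels.sum() == labels.size:
            raise DegenerateDataError(f"split {name} lacks one outcome class")
    thresholds = tuple(float(t) for t in thresholds)
    rng = np.random.default_rng(seed)
    nb_a = _bootstrap_nb(probs_a, labels_a, thresholds, n_boot, rng)
    nb_b = _bootstrap_nb(probs_b, labels_b, thresholds, n_boot, rng)
    delta = nb_a - nb_b
    frac_le = (delta <= 0).mean(axis=0)
    frac_ge = (delta >= 0).mean(axis=0)
    p = np.clip(2.0 * np.minimum(frac_le, frac_ge), 0.0, 1.0)
    return NbComparison(
        period_a=str(period_a),
        period_b=str(period_b),
        thresholds=thresholds,
        p_values=tuple(float(x) for x in p),
        n_boot=n_boot,
        seed=seed,
    )
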