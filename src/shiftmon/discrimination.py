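"""Per-period discrimination metrics and the cross-period stability test.

AUROC is the anchor metric for longitudinal comparison because it is
invariant to incidence and threshold choice.  Its standard error uses the
Hanley–McNeil closed form, and period pairs are compared with an
independent-samples Z-test (different calendar periods contain disjoint
hospital stays, so no pairing structure exists).  AUPRC (average precision)
is reported alongside but never tested across periods — it is strongly
prevalence-dependent.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import DegenerateDataError, UndefinedStatisticError

__all__ = [
    "RocSummary",
    "ComparisonResult",
    "auroc",
    "auprc",
    "hanley_mcneil_se",
    "auroc_z_test",
    "roc_summary",
    "pairwise_auroc_tests",
    "summarize_yearly",
]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DegenerateDataError("scores and labels must be 1-D and equal length")
    if not np.isin(labels, (0, 1)).all():
        raise DegenerateDataError("labels must be 0/1")
    return scores, labels.astype(int)


def auroc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative, ties
    half-credited (Mann–Whitney): (concordant + 0.5 * tied) / (n_pos * n_neg).

    Rank-based; exactly equal to exhaustive pair counting.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks give ties half credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision: sum over distinct-score thresholds of
    precision * recall increment (step interpolation, not trapezoidal)."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise DegenerateDataError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score block (distinct thresholds)
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def hanley_mcneil_se(auroc_value: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of an AUROC ``A``:

    SE^2 = [A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)] / (n_pos n_neg)

    with Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise DegenerateDataError("n_pos and n_neg must each be >= 1")
    a = float(auroc_value)
    if not 0.0 <= a <= 1.0:
        raise DegenerateDataError(f"AUROC must lie in [0, 1], got {a}")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


@dataclasses.dataclass(frozen=True)
class RocSummary:
    """Discrimination summary of one period's test split."""

    period: str
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    se_auroc: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Two-sided independent-samples Z-test between two period AUROCs."""

    period_a: str
    period_b: str
    z: float
    p_value: float
    significant_at_0_05: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def roc_summary(scores, labels, period: str = "") -> RocSummary:
    """Compute AUROC, AUPRC and the Hanley–McNeil SE for one period."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    a = auroc(scores, labels)
    return RocSummary(
        period=str(period),
        auroc=a,
        auprc=auprc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
        se_auroc=hanley_mcneil_se(a, n_pos, n_neg),
    )


def auroc_z_test(a: RocSummary, b: RocSummary) -> ComparisonResult:
    """Z = (A_a - A_b) / sqrt(SE_a^2 + SE_b^2), two-sided normal p-value.

    Independent-samples form: distinct periods contain disjoint cases.
    """
    pooled = math.hypot(a.se_auroc, b.se_auroc)
    if pooled == 0.0:
        if a.auroc == b.auroc:
            z = 0.0
        else:
            raise UndefinedStatisticError(
                "both standard errors are zero but the AUROCs differ"
            )
    else:
        z = (a.auroc - b.auroc) / pooled
    p = float(2.0 * norm.sf(abs(z)))
    return ComparisonResult(
        period_a=a.period,
        period_b=b.period,
        z=float(z),
        p_value=min(p, 1.0),
        significant_at_0_05=p < 0.05,
    )


def pairwise_auroc_tests(summaries: list[RocSummary]) -> list[ComparisonResult]:
    """All-pairs Z-tests, in the order the summaries are given."""
    return [auroc_z_test(a, b) for a, b in itertools.combinations(summaries, 2)]


def summarize_yearly(values) -> tuple[float, float]:
    """Mean and population SD of yearly percentage metrics, in the reporting
    convention used throughout the package's tables: the mean is rounded
    half-up to 2 decimals; the population SD (denominator n) is truncated
    at 2 decimals.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateDataError("need at least 2 yearly values to summarise")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    mean2 = float(Decimal(repr(mean)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    sd2 = float(Decimal(repr(sd)).quantize(Decimal("0.01"), rounding=ROUND_FLOOR))
    return mean2, sd2


def metrics_table(summaries: list[RocSummary]) -> pd.DataFrame:
    """Per-period metrics table: period,n,n_pos,incidence,auroc,se,auprc."""
    rows = []
    for s in summaries:
        n = s.n_pos + s.n_neg
        rows.append(
            {
                "period": s.period,
                "n": n,
                "n_pos": s.n_pos,
                "incidence": s.n_pos / n,
                "auroc": s.auroc,
                "se": s.se_auroc,
                "auprc": s.auprc,
            }
        )
    return pd.DataFrame(rows)
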