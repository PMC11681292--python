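"""Shared fixtures: small synthetic cohorts reused across test modules.

Session-scoped because generation at n>=50,000 dominates test time; all
fixtures are pure functions of a fixed seed, so sharing them cannot leak
state between tests.
"""

import numpy as np
import pytest

from shiftmon import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Four calibrated periods of 20,000 cases (the default study
    conditions)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def drifted_cohort():
    """Same conditions but a +1 logit overestimation offset injected in the
    final period only."""
    return generate_cohort(CohortConfig(miscal_offset=(0.0, 0.0, 0.0, 1.0), seed=7))


@pytest.fixture(scope="session")
def big_calibrated_split():
    """Single calibrated period of 100,000 cases with a 50,000-case
    calibration split, for parameter-recovery and large-n calibration
    checks."""
    return generate_cohort(
        CohortConfig(periods=("p",), n_per_period=100_000, calib_fraction=0.5, seed=11)
    )


def pair_counting_auroc(scores, labels) -> float:
    """Independent AUROC oracle: exhaustive concordant/tied pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    concordant = (pos[:, None] > neg[None, :]).sum()
    tied = (pos[:, None] == neg[None, :]).sum()
    return float((concordant + 0.5 * tied) / (pos.size * neg.size))


def brute_force_threshold(probs, labels) -> float:
    """Independent threshold oracle: scan every candidate, keep the first
    (smallest) minimiser of |FNR - FPR|."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_obj, best_t = None, None
    for t in sorted(set(probs.tolist()) | {0.0, 1.0}):
        alert = probs >= t
        fpr = (alert & (labels == 0)).sum() / n_neg
        fnr = (~alert & (labels == 1)).sum() / n_pos
        obj = abs(fnr - fpr)
        if best_obj is None or obj < best_obj:
            best_obj, best_t = obj, t
    return best_t
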