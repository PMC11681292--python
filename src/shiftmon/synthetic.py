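"""Synthetic scored-cohort simulator.

Deployed risk models emit one probability per hospital stay; monitoring them
longitudinally needs per-period cohorts whose ground truth is *known*.  This
module generates such cohorts from an equal-variance binormal latent model:

* each case's outcome is Bernoulli(pi_y) with a per-period incidence pi_y;
* a latent severity score z is Normal(mu_pos, sigma) for cases and
  Normal(mu_neg, sigma) for controls, so the true AUROC has the closed form
  Phi((mu_pos - mu_neg) / (sigma * sqrt(2)));
* the Bayes posterior P(outcome | z, pi_y) is exactly logistic in z, which
  makes "perfectly calibrated" well defined — ``true_prob`` stores it;
* miscalibration is injected on the logit scale,
  ``raw_score = sigmoid(a_mis * logit(true_prob) + b_mis)``, the same affine
  family that Platt scaling inverts, so injected drift is exactly
  recoverable.  ``(a_mis, b_mis) = (1, 0)`` is the calibrated identity; a
  positive offset makes the model overestimate risk.

The generator also provides the two dataset-perturbation experiments used to
probe whether an apparent calibration shift is an artefact of sample size or
incidence: label-agnostic downsampling and incidence thinning (random removal
of positives).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .exceptions import ConfigurationError, DegenerateDataError, InvalidTargetError
from .io import CALIBRATION, COLUMNS, TEST, read_cases, write_cases

__all__ = [
    "CohortConfig",
    "ScoredCohort",
    "generate_cohort",
    "expected_auroc",
    "binormal_auroc",
    "downsample_cohort",
    "thin_incidence",
]


def _per_period(value, periods, field: str) -> tuple[float, ...]:
    """Broadcast a scalar to one value per period; validate length otherwise."""
    if np.isscalar(value):
        return tuple(float(value) for _ in periods)
    value = tuple(float(v) for v in value)
    if len(value) != len(periods):
        raise ConfigurationError(
            f"{field}: expected {len(periods)} values (one per period), got {len(value)}"
        )
    return value


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a synthetic scored cohort.

    Scalars for ``incidence``, ``miscal_slope`` and ``miscal_offset`` are
    broadcast across periods; sequences must have one entry per period.

    Defaults describe a stable, well-calibrated deployment: four yearly
    periods of 20,000 cases, incidence 15% (an AKI-like use case), latent
    separation ``mu_pos - mu_neg = 2`` with ``sigma = 1`` (true AUROC 0.9214),
    no miscalibration, and 10% of cases reserved for the calibration /
    threshold-selection split.
    """

    periods: Sequence[str] = ("2018", "2019", "2020", "2021")
    n_per_period: int = 20_000
    incidence: float | Sequence[float] = 0.15
    mu_pos: float = 2.0
    mu_neg: float = 0.0
    sigma: float = 1.0
    miscal_slope: float | Sequence[float] = 1.0
    miscal_offset: float | Sequence[float] = 0.0
    calib_fraction: float = 0.10
    with_times: bool = False
    seed: int = 0

    def __post_init__(self):
        periods = tuple(str(p) for p in self.periods)
        if len(periods) == 0:
            raise ConfigurationError("periods: must be nonempty")
        if len(set(periods)) != len(periods):
            raise ConfigurationError("periods: labels must be unique")
        object.__setattr__(self, "periods", periods)
        if self.n_per_period < 20:
            raise ConfigurationError("n_per_period: must be >= 20")
        inc = _per_period(self.incidence, periods, "incidence")
        if any(not 0.0 < p < 1.0 for p in inc):
            raise ConfigurationError("incidence: every value must lie strictly in (0, 1)")
        object.__setattr__(self, "incidence", inc)
        if not self.sigma > 0:
            raise ConfigurationError("sigma: must be > 0")
        object.__setattr__(
            self, "miscal_slope", _per_period(self.miscal_slope, periods, "miscal_slope")
        )
        object.__setattr__(
            self, "miscal_offset", _per_period(self.miscal_offset, periods, "miscal_offset")
        )
        if not 0.0 < self.calib_fraction <= 0.5:
            raise ConfigurationError("calib_fraction: must lie in (0, 0.5]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["periods"] = list(self.periods)
        for key in ("incidence", "miscal_slope", "miscal_offset"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**dict(d))


@dataclasses.dataclass
class ScoredCohort:
    """A scored-cases table partitioned into a calibration split and
    per-period test splits (the ``split`` column holds ``calibration`` or
    ``test``)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise DegenerateDataError(f"cohort frame missing columns {missing}")
        splits = set(self.frame["split"].unique())
        if not splits <= {CALIBRATION, TEST}:
            raise DegenerateDataError(
                f"split column must contain only {{{CALIBRATION!r}, {TEST!r}}}, got {splits}"
            )
        for period in self.periods:
            if ((self.frame["period"] == period) & (self.frame["split"] == TEST)).sum() == 0:
                raise DegenerateDataError(f"test split for period {period!r} is empty")

    @property
    def periods(self) -> list[str]:
        """Period labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["period"]))

    @property
    def n(self) -> int:
        return len(self.frame)

    def calibration(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == CALIBRATION]

    def test(self, period: str) -> pd.DataFrame:
        sel = (self.frame["split"] == TEST) & (self.frame["period"] == str(period))
        return self.frame[sel]

    def test_splits(self) -> dict[str, pd.DataFrame]:
        return {p: self.test(p) for p in self.periods}

    def incidence(self, period: str | None = None) -> float:
        frame = self.frame if period is None else self.test(period)
        return float(frame["label"].mean())

    def to_csv(self, path: str | Path) -> None:
        write_cases(self.frame, path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoredCohort":
        return cls(read_cases(path))


def binormal_auroc(mu_pos: float, mu_neg: float, sigma: float) -> float:
    """Closed-form AUROC of the equal-variance binormal model,
    Phi((mu_pos - mu_neg) / (sigma * sqrt(2)))."""
    if not sigma > 0:
        raise ConfigurationError("sigma: must be > 0")
    return float(norm.cdf((mu_pos - mu_neg) / (sigma * np.sqrt(2.0))))


def expected_auroc(config: CohortConfig) -> float:
    """Ground-truth AUROC implied by a cohort configuration."""
    return binormal_auroc(config.mu_pos, config.mu_neg, config.sigma)


def generate_cohort(config: CohortConfig) -> ScoredCohort:
    """Draw a scored cohort from the binormal model; deterministic given
    ``config.seed``.

    For each case: ``label ~ Bernoulli(pi_y)``; latent
    ``z ~ Normal(mu_pos, sigma)`` if case else ``Normal(mu_neg, sigma)``;
    ``true_prob`` is the exact Bayes posterior ``P(label=1 | z, pi_y)``;
    ``raw_score = sigmoid(a_mis * logit(true_prob) + b_mis)``.  The
    calibration split is ``round(calib_fraction * N)`` cases drawn uniformly
    without replacement across all periods.
    """
    rng = np.random.default_rng(config.seed)
    delta = config.mu_pos - config.mu_neg
    mid = 0.5 * (config.mu_pos + config.mu_neg)
    pieces = []
    for idx, period in enumerate(config.periods):
        n = config.n_per_period
        pi = config.incidence[idx]
        label = (rng.random(n) < pi).astype(int)
        mu = np.where(label == 1, config.mu_pos, config.mu_neg)
        z = mu + config.sigma * rng.standard_normal(n)
        # log-likelihood ratio of the two equal-variance normals + prior odds
        eta = logit(pi) + (delta / config.sigma**2) * (z - mid)
        true_prob = expit(eta)
        raw_score = expit(config.miscal_slope[idx] * eta + config.miscal_offset[idx])
        piece = pd.DataFrame(
            {
                "case_id": [f"{period}-{i:06d}" for i in range(n)],
                "period": period,
                "label": label,
                "raw_score": raw_score,
                "true_prob": true_prob,
                "onset_time": np.nan,
                "los": np.nan,
            }
        )
        if config.with_times:
            los = np.minimum(np.ceil(rng.exponential(7.0, n)), 90.0)
            onset = np.where(label == 1, rng.random(n) * los, np.nan)
            piece["los"] = los
            piece["onset_time"] = onset
        pieces.append(piece)
    frame = pd.concat(pieces, ignore_index=True)
    n_total = len(frame)
    n_cal = int(round(config.calib_fraction * n_total))
    cal_idx = rng.choice(n_total, size=n_cal, replace=False)
    split = np.full(n_total, TEST, dtype=object)
    split[cal_idx] = CALIBRATION
    frame["split"] = split
    return ScoredCohort(frame.reindex(columns=COLUMNS))


def _split_groups(cohort: ScoredCohort):
    """Deterministic iteration order: calibration split first, then each
    period's test split."""
    yield CALIBRATION, cohort.frame.index[cohort.frame["split"] == CALIBRATION]
    for period in cohort.periods:
        sel = (cohort.frame["split"] == TEST) & (cohort.frame["period"] == period)
        yield period, cohort.frame.index[sel]


def downsample_cohort(cohort: ScoredCohort, fraction: float, seed: int) -> ScoredCohort:
    """Subsample every split (calibration and each period's test split)
    without replacement to ``round(fraction * n)`` cases, label-agnostically.

    Retained rows are unchanged and keep their original order.
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidTargetError(f"fraction must lie in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for name, index in _split_groups(cohort):
        m = int(round(fraction * len(index)))
        if m == 0:
            raise InvalidTargetError(f"downsampling empties split {name!r}")
        keep.append(rng.choice(index.to_numpy(), size=m, replace=False))
    kept = np.sort(np.concatenate(keep))
    return ScoredCohort(cohort.frame.loc[kept].reset_index(drop=True))


def _positives_to_keep(n_pos: int, n_neg: int, target: float) -> int:
    """Positive count k in [0, n_pos] minimising |k/(k+n_neg) - target|;
    ties broken toward the smaller k."""
    k0 = target * n_neg / (1.0 - target)
    candidates = sorted({int(np.floor(k0)), int(np.ceil(k0))})
    candidates = [min(max(k, 0), n_pos) for k in candidates]
    return min(candidates, key=lambda k: (abs(k / (k + n_neg) - target), k))


def thin_incidence(cohort: ScoredCohort, target_incidence: float, seed: int) -> ScoredCohort:
    """Randomly remove positive cases from every split until each split's
    incidence is as close as achievable to ``target_incidence``.

    Negatives are untouched; this operation only thins (the target must be
    below every split's current incidence).
    """
    if not 0.0 < target_incidence < 1.0:
        raise InvalidTargetError(f"target_incidence must lie in (0, 1), got {target_incidence}")
    rng = np.random.default_rng(seed)
    drop: list[np.ndarray] = []
    for name, index in _split_groups(cohort):
        labels = cohort.frame.loc[index, "label"].to_numpy()
        n_pos = int(labels.sum())
        n_neg = len(labels) - n_pos
        if n_pos == 0 or n_neg == 0:
            raise DegenerateDataError(f"split {name!r} lacks one outcome class")
        current = n_pos / (n_pos + n_neg)
        if target_incidence >= current:
            raise InvalidTargetError(
                f"split {name!r}: target {target_incidence:.4f} >= current "
                f"incidence {current:.4f}; thinning only reduces incidence"
            )
        k = _positives_to_keep(n_pos, n_neg, target_incidence)
        pos_index = index.to_numpy()[labels == 1]
        drop.append(rng.choice(pos_index, size=n_pos - k, replace=False))
    dropped = np.concatenate(drop)
    kept = cohort.frame.index.difference(dropped)
    return ScoredCohort(cohort.frame.loc[kept].reset_index(drop=True))
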