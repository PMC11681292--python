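"""Optional plot output: reliability diagrams and decision curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .calibration import ReliabilityCurve
from .decision import DecisionCurve


def reliability_diagram(curves: list[ReliabilityCurve], path: str | Path) -> None:
    """One reliability diagram per figure; each curve labelled by period,
    with Wilson 95% CI bars and the identity diagonal."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for curve in curves:
        err = [curve.observed - curve.ci_low, curve.ci_high - curve.observed]
        ax.errorbar(
            curve.mean_pred, curve.observed, yerr=err, marker="o", capsize=2,
            label=curve.period or None,
        )
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    if any(c.period for c in curves):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def decision_curve_plot(curves: list[DecisionCurve], path: str | Path) -> None:
    """Net benefit of model (solid), treat-all (dotted) and treat-none
    (grey) per period."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        (line,) = ax.plot(curve.thresholds, curve.nb_model, label=curve.period or "model")
        ax.plot(curve.thresholds, curve.nb_all, ls=":", color=line.get_color(), lw=1)
    ax.axhline(0.0, color="grey", lw=1)
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
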