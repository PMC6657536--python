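"""Figure helpers: curve/velocity/acceleration panels and phase portraits."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phase import PhaseLinearFit, PhaseSmoothFit
from .splines import CurveEstimate, PenalizedFit, predict_curve

__all__ = ["plot_curve_panels", "plot_phase"]


def _panel(ax, est: CurveEstimate, ylabel: str, zero_line: bool):
    ax.fill_between(est.grid, est.lower, est.upper, color="0.8", label=f"{est.level:.0%} CI")
    ax.plot(est.grid, est.estimate, color="C0")
    if zero_line:
        ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel(ylabel)


def plot_curve_panels(
    fit: PenalizedFit,
    grid: np.ndarray | None = None,
    level: float = 0.95,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Mean curve, velocity and acceleration with pointwise bands.

    The derivative panels carry a zero reference line: the times where the
    velocity crosses zero mark turning points of aggregation, and where
    the acceleration crosses zero the rate stops changing.
    """
    if grid is None:
        grid = np.linspace(float(fit.times.min()), float(fit.times.max()), 300)
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    labels = ["aggregation (%)", "velocity (%/min)", "acceleration (%/min$^2$)"]
    for m, (ax, lab) in enumerate(zip(axes, labels)):
        _panel(ax, predict_curve(fit, grid, m, level), lab, zero_line=m > 0)
    axes[-1].set_xlabel("time (min)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_phase(
    points,
    law: PhaseLinearFit | PhaseSmoothFit,
    path: str | Path | None = None,
    title: str | None = None,
    level: float = 0.95,
):
    """Velocity against aggregation with the fitted law and zero-velocity line."""
    y = points["aggregation"].to_numpy(float)
    v = points["velocity"].to_numpy(float)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(y, v, ".", ms=3, color="0.5", label="phase points")
    ygrid = np.linspace(y.min(), y.max(), 200)
    if isinstance(law, PhaseSmoothFit):
        est = law.law(ygrid, level=level)
        ax.fill_between(ygrid, est.lower, est.upper, color="0.85")
        ax.plot(ygrid, est.estimate, color="C1", label="smooth law")
        for ystar, flag in law.fixed_points:
            ax.plot([ystar], [0.0], "o", color="C3" if flag == "stable" else "C2")
    else:
        ax.plot(ygrid, law.law(ygrid), color="C1", label="linear law")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("aggregation (%)")
    ax.set_ylabel("velocity (%/min)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
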