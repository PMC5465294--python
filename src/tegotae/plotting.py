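"""Gait-diagram and force-profile figures."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .gait import GaitDiagram
from .legs import LEGS
from .simulate import TrialSeries

__all__ = ["plot_gait_diagram", "plot_forces"]


def plot_gait_diagram(diagram: GaitDiagram, path: Union[str, Path, None] = None,
                      ax: Optional[plt.Axes] = None):
    """Stance raster as horizontal bars, one row per leg (L1 on top)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    t = diagram.times
    for row, leg in enumerate(LEGS):
        col = diagram.stance[:, leg.index]
        ax.fill_between(t, row + 0.1, row + 0.9, where=col > 0,
                        step="post", color="0.2")
    ax.set_yticks([r + 0.5 for r in range(6)])
    ax.set_yticklabels([leg.label for leg in LEGS])
    ax.invert_yaxis()
    ax.set_xlabel("time (s)")
    ax.set_xlim(t[0], t[-1])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_forces(series: TrialSeries, path: Union[str, Path, None] = None):
    """Per-leg vertical force traces, left column L1-L3, right R1-R3."""
    fig, axes = plt.subplots(3, 2, figsize=(9, 6), sharex=True, sharey=True)
    for leg in LEGS:
        ax = axes[leg.rank - 1][0 if leg.label.startswith("L") else 1]
        ax.plot(series.t, series.forces[:, leg.index], lw=0.8, label=leg.label)
        ax.legend(loc="upper right", frameon=False)
        ax.set_ylabel("N^V (N)")
    for ax in axes[-1]:
        ax.set_xlabel("time (s)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
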