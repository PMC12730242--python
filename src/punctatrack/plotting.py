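"""Figures: classified trajectory maps, step-size distributions, rosettes."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .mixture import StepMixtureFit, StepSample, evaluate_mixture_pdf
from .trajectory import Trajectory

__all__ = ["plot_trajectory_map", "plot_step_distribution", "plot_directed_rosette",
           "CLASS_COLORS"]

#: Conventional class colours: stationary dark blue, Brownian green,
#: directed orange.
CLASS_COLORS = {"immobile": "#00008b", "brownian": "#2ca02c",
                "directed": "#ff7f0e"}


def plot_trajectory_map(trajs: Sequence[Trajectory], labels: Mapping[int, str],
                        ax=None):
    """Overlay every trajectory, coloured by its motion class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for traj in trajs:
        color = CLASS_COLORS.get(labels.get(traj.id, "brownian"), "grey")
        ax.plot(traj.x, traj.y, lw=0.8, color=color)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.invert_yaxis()  # image convention: y down
    return ax


def plot_step_distribution(sample: StepSample, fit: StepMixtureFit, ax=None,
                           bins: int = 50):
    """Step-size histogram with the fitted mixture decomposition shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    steps = sample.steps[sample.steps > 0]
    ax.hist(steps, bins=bins, density=True, color="0.3", alpha=0.35,
            label="steps")
    grid = np.linspace(0, max(steps.max(), 4 * fit.s2), 400)
    curves = evaluate_mixture_pdf(fit, grid)
    fills = {"rayleigh1": CLASS_COLORS["immobile"],
             "rayleigh2": CLASS_COLORS["brownian"],
             "gaussian": CLASS_COLORS["directed"]}
    for name, color in fills.items():
        if name in curves:
            ax.fill_between(grid, curves[name], color=color, alpha=0.4,
                            label=name)
    ax.plot(grid, curves["total"], "k-", lw=1.2, label="total")
    ax.set_xlabel("step size r (µm)")
    ax.set_ylabel("probability density (1/µm)")
    ax.legend(fontsize=8)
    return ax


def plot_directed_rosette(trajs: Sequence[Trajectory], ax=None):
    """All directed trajectories re-origined at (0, 0)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for traj in trajs:
        ax.plot(traj.x - traj.x[0], traj.y - traj.y[0], lw=1.0)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("Δx (µm)")
    ax.set_ylabel("Δy (µm)")
    return ax
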