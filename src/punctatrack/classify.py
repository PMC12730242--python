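"""Trajectory classification and per-cell / per-condition summaries.

Each accepted trajectory is sorted into one of three motion classes using
the cell's fitted step-size scales s1 (localization precision) and s2
(diffusive step scale):

1. *immobile* — both the total (net start-to-end) displacement and the
   largest single step are below 12 * s1, i.e. the particle never leaves a
   diffraction-limited neighbourhood of its starting point (~240 nm for
   s1 ~ 20 nm), with headroom for occasional apparent steps from slow
   whole-cell drift;
2. *directed* — the total displacement exceeds 1.5 * s2 * sqrt(n) (n =
   number of steps; a diffusing particle's expected excursion is
   s2 * sqrt(n), so half again more indicates transport), or the fitted MSD
   exponent alpha exceeds 1.1;
3. *brownian* — everything else.

The immobile test is evaluated first so that a tightly confined trajectory
with a tiny alpha cannot fall through to the directed branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixture import StepMixtureFit
from .trajectory import Trajectory

__all__ = [
    "ClassificationConstants",
    "MotionLabel",
    "CellSummary",
    "ConditionSummary",
    "ConditionComparison",
    "classify_features",
    "classify_trajectory",
    "summarize_cell",
    "aggregate_condition",
    "compare_conditions",
    "LABELS",
]

LABELS = ("immobile", "brownian", "directed")

RULES = (
    "total_and_max_step_lt_12s1",
    "displacement_gt_1p5_s2_sqrt_n",
    "alpha_gt_1p1",
    "default_diffusive",
)


@dataclass(frozen=True)
class ClassificationConstants:
    """The three classification constants; defaults are the canonical ones."""

    immobile_factor: float = 12.0
    directed_factor: float = 1.5
    alpha_threshold: float = 1.1


@dataclass(frozen=True)
class MotionLabel:
    label: str
    rule_fired: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.rule_fired not in RULES:
            raise ValueError(f"unknown rule {self.rule_fired!r}")


def classify_features(total_displacement: float, largest_step: float,
                      n_steps: int, alpha: float | None,
                      s1: float, s2: float,
                      constants: ClassificationConstants = ClassificationConstants(),
                      ) -> MotionLabel:
    """Classify from precomputed features.

    ``alpha`` may be None when the power-law fit failed (or did not
    converge); the displacement rules then decide alone.
    """
    immobile_ceiling = constants.immobile_factor * s1
    if total_displacement < immobile_ceiling and largest_step < immobile_ceiling:
        return MotionLabel("immobile", "total_and_max_step_lt_12s1")
    if total_displacement > constants.directed_factor * s2 * np.sqrt(n_steps):
        return MotionLabel("directed", "displacement_gt_1p5_s2_sqrt_n")
    if alpha is not None and alpha > constants.alpha_threshold:
        return MotionLabel("directed", "alpha_gt_1p1")
    return MotionLabel("brownian", "default_diffusive")


def classify_trajectory(traj: Trajectory, fit: StepMixtureFit,
                        alpha: float | None = None,
                        constants: ClassificationConstants = ClassificationConstants(),
                        ) -> MotionLabel:
    """Classify one trajectory given its cell's step-mixture fit."""
    return classify_features(
        total_displacement=traj.net_displacement,
        largest_step=traj.largest_step,
        n_steps=traj.n_steps,
        alpha=alpha,
        s1=fit.s1,
        s2=fit.s2,
        constants=constants,
    )


@dataclass
class CellSummary:
    """Per-cell class fractions and class-conditional motion statistics.

    D_a and alpha are averaged over Brownian-labeled trajectories only;
    v_max over directed-labeled trajectories only.  Fields are NaN when the
    corresponding class is empty.
    """

    cell_id: str
    n_trajectories: int
    pct_immobile: float
    pct_brownian: float
    pct_directed: float
    D_a_mean: float
    D_a_sd: float
    alpha_mean: float
    alpha_sd: float
    v_max_mean: float
    v_max_sd: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def summarize_cell(table: pd.DataFrame, cell_id: str = "cell") -> CellSummary:
    """Summarize one cell from its per-trajectory metrics table.

    ``table`` must carry columns ``label``, ``D_a``, ``alpha`` and ``v_max``
    (one row per labeled trajectory, NaN where a metric is unavailable).
    """
    if len(table) == 0:
        raise ValueError("cannot summarize a cell with no labeled trajectories")
    n = len(table)
    counts = table["label"].value_counts()
    pct = {lab: 100.0 * counts.get(lab, 0) / n for lab in LABELS}
    brown = table[table["label"] == "brownian"]
    directed = table[table["label"] == "directed"]
    d_mean, d_sd = _mean_sd(brown["D_a"].to_numpy(dtype=float))
    a_mean, a_sd = _mean_sd(brown["alpha"].to_numpy(dtype=float))
    v_mean, v_sd = _mean_sd(directed["v_max"].to_numpy(dtype=float))
    return CellSummary(
        cell_id=cell_id, n_trajectories=n,
        pct_immobile=pct["immobile"], pct_brownian=pct["brownian"],
        pct_directed=pct["directed"],
        D_a_mean=d_mean, D_a_sd=d_sd,
        alpha_mean=a_mean, alpha_sd=a_sd,
        v_max_mean=v_mean, v_max_sd=v_sd,
    )


_AGG_METRICS = ("pct_immobile", "pct_brownian", "pct_directed",
                "D_a_mean", "alpha_mean", "v_max_mean")


@dataclass
class ConditionSummary:
    """Across-cell mean +/- SD of each per-cell metric for one condition."""

    condition: str
    n_cells: int
    n_trajectories: int
    means: dict
    sds: dict
    single_cell: bool = False

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_cells": self.n_cells,
            "n_trajectories": self.n_trajectories,
            "means": dict(self.means),
            "sds": dict(self.sds),
            "single_cell": self.single_cell,
        }


def aggregate_condition(cells: Sequence[CellSummary],
                        condition: str = "condition") -> ConditionSummary:
    """Unweighted across-cell mean and SD of each cell-level metric.

    With a single cell the SDs are reported as 0 and flagged.
    """
    if not cells:
        raise ValueError("aggregate_condition requires at least one cell")
    means, sds = {}, {}
    single = len(cells) == 1
    for metric in _AGG_METRICS:
        vals = np.array([getattr(c, metric) for c in cells], dtype=float)
        m, sd = _mean_sd(vals)
        means[metric] = m
        sds[metric] = 0.0 if single else sd
    return ConditionSummary(
        condition=condition,
        n_cells=len(cells),
        n_trajectories=int(sum(c.n_trajectories for c in cells)),
        means=means,
        sds=sds,
        single_cell=single,
    )


@dataclass
class ConditionComparison:
    """One-way ANOVA across conditions plus Tukey HSD pairwise p-values."""

    groups: list[str]
    anova_F: float
    anova_p: float
    tukey_p: dict

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "tukey_p": {f"{a}|{b}": p for (a, b), p in self.tukey_p.items()},
        }


def compare_conditions(groups: Mapping[str, Sequence[float]]) -> ConditionComparison:
    """One-way ANOVA with Tukey's post hoc test over per-cell metric values.

    Degenerate input with zero between-group variance (e.g. identical
    groups) yields F = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    samples = [np.asarray(groups[name], dtype=float) for name in names]
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")

    grand = np.concatenate(samples)
    group_means = np.array([s.mean() for s in samples])
    ss_between = sum(s.size * (m - grand.mean()) ** 2
                     for s, m in zip(samples, group_means))
    if np.isclose(ss_between, 0.0, atol=1e-30):
        F, p = 0.0, 1.0
        tukey_p = {(a, b): 1.0 for i, a in enumerate(names)
                   for b in names[i + 1:]}
        return ConditionComparison(names, F, p, tukey_p)

    F, p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    tukey_p = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            tukey_p[(a, names[j])] = float(tukey.pvalue[i, j])
    return ConditionComparison(names, float(F), float(p), tukey_p)
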