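"""End-to-end per-cell analysis: QC -> metrics -> mixture -> classification.

This is the glue the CLI (and any script) calls; each stage lives in its own
module and is individually testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as mx
from .classify import (CellSummary, ClassificationConstants, classify_features,
                       summarize_cell)
from .mixture import StepMixtureFit, fit_rayleigh_mixture, pool_displacements
from .qc import QcParams, QcReport, filter_trajectories
from .tracking import AcquisitionGeometry
from .trajectory import Trajectory

__all__ = ["CellResult", "compute_trajectory_metrics", "analyze_cell"]


def compute_trajectory_metrics(trajs: Sequence[Trajectory], tau: float,
                               fit_window: tuple[float, float] = mx.DEFAULT_FIT_WINDOW,
                               ) -> pd.DataFrame:
    """Per-trajectory metrics table.

    One row per trajectory with the MSD power-law fit (NaN where the fit
    failed), the maximum-velocity estimate and the displacement features
    used downstream by QC-independent classification.
    """
    rows = []
    for traj in trajs:
        row = {
            "traj_id": traj.id,
            "n_obs": traj.n_obs,
            "n_steps": traj.n_steps,
            "duration": traj.duration,
            "total_displacement": traj.net_displacement,
            "largest_step": traj.largest_step,
            "mean_intensity": traj.mean_intensity,
            "D_a": np.nan,
            "alpha": np.nan,
            "fit_ok": False,
            "fit_goodness": np.nan,
            "v_max": np.nan,
            "v_max_flagged": False,
        }
        if traj.n_obs >= 2:
            fit = mx.try_fit_power_law(mx.compute_msd(traj, tau), fit_window)
            if fit is not None:
                row.update(D_a=fit.D_a, alpha=fit.alpha, fit_ok=True,
                           fit_goodness=fit.goodness)
        try:
            vel = mx.max_velocity(traj, tau)
            row.update(v_max=vel.v_max, v_max_flagged=vel.no_positive_correlation)
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CellResult:
    """Everything the analysis produced for one cell."""

    cell_id: str
    qc: QcReport
    metrics: pd.DataFrame            # accepted trajectories, with labels
    mixture: StepMixtureFit | None
    summary: CellSummary | None


def analyze_cell(trajs: Sequence[Trajectory], geometry: AcquisitionGeometry,
                 qc_params: QcParams = QcParams(),
                 constants: ClassificationConstants = ClassificationConstants(),
                 fit_window: tuple[float, float] = mx.DEFAULT_FIT_WINDOW,
                 with_gaussian: str | bool = "auto",
                 cell_id: str = "cell",
                 skip_qc: bool = False) -> CellResult:
    """Run the full per-cell analysis chain on raw trajectories.

    QC rejects unusable trajectories; the survivors' single-frame steps are
    pooled into the cell's step-size distribution, whose fitted scales s1/s2
    drive the per-trajectory classification; finally the cell summary
    collects class fractions and class-conditional statistics.
    """
    tau = geometry.tau
    trajs = list(trajs)
    if skip_qc:
        qc = QcReport([t.id for t in trajs], [], float("nan"), float("nan"),
                      qc_params)
    else:
        qc = filter_trajectories(trajs, qc_params, geometry)
    accepted = [t for t in trajs if t.id in set(qc.accepted)]

    table = compute_trajectory_metrics(accepted, tau, fit_window)
    if not accepted:
        return CellResult(cell_id, qc, table, None, None)

    sample = pool_displacements(accepted, tau, cell_id=cell_id)
    if sample.steps.size == 0 or not np.any(sample.steps > 0):
        return CellResult(cell_id, qc, table, None, None)
    fit = fit_rayleigh_mixture(sample, with_gaussian=with_gaussian)

    labels, rules = [], []
    for _, row in table.iterrows():
        alpha = float(row["alpha"]) if row["fit_ok"] else None
        lab = classify_features(row["total_displacement"], row["largest_step"],
                                int(row["n_steps"]), alpha, fit.s1, fit.s2,
                                constants)
        labels.append(lab.label)
        rules.append(lab.rule_fired)
    table = table.assign(label=labels, rule_fired=rules)

    summary = summarize_cell(table, cell_id=cell_id)
    return CellResult(cell_id, qc, table, fit, summary)
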