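"""Trajectory quality control.

Rejects trajectories before motion analysis when any of the following fires,
in this fixed order (the first failing rule is recorded):

1. ``too_short`` — observed in fewer than ``min_frames`` frames;
2. ``jump_successive`` — a displacement between successive observed frames
   exceeds ``max_step_um`` micrometres;
3. ``jump_gap`` — a displacement across a one-frame detection gap exceeds
   ``max_gap_step_px`` pixels;
4. ``low_intensity`` — mean particle intensity more than ``intensity_sd_k``
   standard deviations below the population mean;
5. ``low_coverage`` — detected in less than ``min_detection_fraction`` of the
   trajectory's duration.

The intensity population statistics are computed over the per-trajectory
mean intensities of *all* input trajectories, before any rejection, and are
echoed in the report so a re-run on the accepted subset can reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracking import AcquisitionGeometry
from .trajectory import Trajectory

__all__ = ["QcParams", "QcReport", "filter_trajectories", "REASON_CODES"]

REASON_CODES = ("too_short", "jump_successive", "jump_gap",
                "low_intensity", "low_coverage")


@dataclass(frozen=True)
class QcParams:
    """Inclusion thresholds; the displacement limits are per-cell tunables."""

    min_frames: int = 8
    max_step_um: float = 1.0
    max_gap_step_px: float = 3.0
    intensity_sd_k: float = 1.0
    min_detection_fraction: float = 0.70

    def __post_init__(self) -> None:
        if min(self.min_frames, self.max_step_um, self.max_gap_step_px,
               self.intensity_sd_k) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.min_detection_fraction <= 1:
            raise ValueError("min_detection_fraction must lie in (0, 1]")


@dataclass
class QcReport:
    accepted: list[int]
    rejected: list[tuple[int, str]]
    intensity_mean: float
    intensity_sd: float
    params: QcParams = field(default=None)

    @property
    def n_input(self) -> int:
        return len(self.accepted) + len(self.rejected)

    def to_dict(self) -> dict:
        return {
            "accepted": list(self.accepted),
            "rejected": [{"traj_id": tid, "reason": reason}
                         for tid, reason in self.rejected],
            "intensity_mean": self.intensity_mean,
            "intensity_sd": self.intensity_sd,
            "params": vars(self.params) if self.params is not None else None,
        }


def _first_failure(traj: Trajectory, params: QcParams, d: float,
                   intensity_floor: float) -> str | None:
    if traj.n_obs < params.min_frames:
        return "too_short"
    if np.any(traj.step_displacements(1) > params.max_step_um):
        return "jump_successive"
    if np.any(traj.step_displacements(2) > params.max_gap_step_px * d):
        return "jump_gap"
    if traj.mean_intensity < intensity_floor:
        return "low_intensity"
    if traj.n_obs / traj.duration < params.min_detection_fraction:
        return "low_coverage"
    return None


def filter_trajectories(trajs: Sequence[Trajectory], params: QcParams,
                        geometry: AcquisitionGeometry,
                        population_stats: tuple[float, float] | None = None
                        ) -> QcReport:
    """Partition trajectories into accepted and rejected sets.

    ``population_stats`` (mean, sd of per-trajectory mean intensity) may be
    supplied to freeze the intensity baseline from an earlier pass, which
    makes filtering idempotent on its own accepted set.
    """
    trajs = list(trajs)
    if not trajs:
        return QcReport([], [], float("nan"), float("nan"), params)

    if population_stats is None:
        means = np.array([t.mean_intensity for t in trajs])
        pop_mean = float(means.mean())
        pop_sd = float(means.std(ddof=0))
    else:
        pop_mean, pop_sd = map(float, population_stats)
    floor = pop_mean - params.intensity_sd_k * pop_sd

    accepted: list[int] = []
    rejected: list[tuple[int, str]] = []
    for traj in trajs:
        reason = _first_failure(traj, params, geometry.d, floor)
        if reason is None:
            accepted.append(traj.id)
        else:
            rejected.append((traj.id, reason))
    return QcReport(accepted, rejected, pop_mean, pop_sd, params)
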