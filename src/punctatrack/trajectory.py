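"""Trajectory container shared by every pipeline stage.

A trajectory is the time-ordered sequence of sub-pixel localizations of one
tracked particle.  Positions are stored in micrometres (conversion from pixel
coordinates happens once, at linking or table-reading time), frame indices are
0-based and may contain gaps where the particle went undetected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Per-frame localizations (frame, x, y, intensity) of one particle.

    Parameters
    ----------
    id : int
        Trajectory identifier, unique within one movie/cell.
    frames : array of int
        0-based frame indices, strictly increasing.  Gaps (missing frames)
        are allowed and preserved; downstream statistics that require
        consecutive observations skip them explicitly.
    x, y : array of float
        Sub-pixel particle positions in micrometres.
    intensity : array of float
        Detection intensity (arbitrary units), one value per observation.
    """

    id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is None:
            self.intensity = np.ones_like(self.x)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.intensity) == n):
            raise ValueError(
                f"trajectory {self.id}: frames/x/y/intensity lengths differ"
            )
        if n == 0:
            raise ValueError(f"trajectory {self.id}: empty")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"trajectory {self.id}: frame indices must be strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"trajectory {self.id}: non-finite positions")

    # -- basic size/shape accessors -------------------------------------

    @property
    def n_obs(self) -> int:
        """Number of observations (frames in which the particle was seen)."""
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        """Number of inter-observation steps, n = observations - 1."""
        return self.n_obs - 1

    @property
    def duration(self) -> int:
        """Frames spanned from first to last observation, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))

    @property
    def positions(self) -> np.ndarray:
        """(n_obs, 2) array of (x, y) in micrometres."""
        return np.column_stack([self.x, self.y])

    # -- displacement features used by QC and classification ------------

    def step_displacements(self, frame_gap: int = 1) -> np.ndarray:
        """Euclidean displacements between observations exactly
        ``frame_gap`` frames apart (adjacent rows only).

        ``frame_gap=1`` gives the consecutive-frame steps that feed the
        step-size distribution; ``frame_gap=2`` the one-frame-gap jumps
        checked by quality control.
        """
        df = np.diff(self.frames)
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        sel = df == frame_gap
        return np.hypot(dx[sel], dy[sel])

    @property
    def net_displacement(self) -> float:
        """Straight-line distance from first to last observation (um)."""
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def largest_step(self) -> float:
        """Largest consecutive-frame displacement (um); 0 if none exist."""
        steps = self.step_displacements(1)
        return float(steps.max()) if steps.size else 0.0

    @property
    def mean_intensity(self) -> float:
        return float(self.intensity.mean())

    def translated(self, dx: float, dy: float) -> "Trajectory":
        return Trajectory(self.id, self.frames.copy(), self.x + dx, self.y + dy,
                          self.intensity.copy())

    def rotated(self, angle: float) -> "Trajectory":
        """Rigid rotation about the origin by ``angle`` radians."""
        c, s = np.cos(angle), np.sin(angle)
        return Trajectory(self.id, self.frames.copy(),
                          c * self.x - s * self.y,
                          s * self.x + c * self.y,
                          self.intensity.copy())
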