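"""Per-trajectory motion quantification.

Implements the time-averaged mean-squared displacement and its power-law
fit <r^2(t)> = 4 * D_a * t^alpha over a fixed lag window, the velocity
autocorrelation function, and a maximum-velocity estimate built from the
correlation of successive frame-to-frame velocities.

alpha ~ 1 indicates free diffusion, alpha < 1 constrained diffusion, and
alpha ~ 2 directed transport.  D_a is an *apparent* diffusion coefficient:
for alpha != 1 it is simply the diffusivity implied by the fitted MSD at
t = 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MsdCurve",
    "PowerLawFit",
    "VafCurve",
    "VelocityEstimate",
    "FitFailure",
    "compute_msd",
    "fit_power_law",
    "try_fit_power_law",
    "compute_vaf",
    "max_velocity",
]

#: Default fit window for the MSD power law: lag times from 1 to 10 s.
DEFAULT_FIT_WINDOW = (1.0, 10.0)


class FitFailure(ValueError):
    """The MSD power-law fit could not be performed for this trajectory."""


@dataclass
class MsdCurve:
    """Time-averaged MSD: ``values[i]`` (um^2) at lag ``lags[i]`` (s),
    averaged over ``counts[i]`` observation pairs."""

    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray


@dataclass
class PowerLawFit:
    D_a: float
    alpha: float
    fit_window: tuple[float, float]
    goodness: float
    n_lags: int


@dataclass
class VafCurve:
    """Velocity autocorrelation <v(0).v(t)> (um^2/s^2) per lag (s)."""

    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray


@dataclass
class VelocityEstimate:
    v_max: float
    frame_of_max: int
    no_positive_correlation: bool = False


def compute_msd(traj: Trajectory, tau: float) -> MsdCurve:
    """Time-averaged MSD over all ordered observation pairs.

    For each frame separation k with at least one valid pair, the MSD at lag
    k*tau is the mean squared displacement over every pair of observations
    exactly k frames apart.  Gapped trajectories simply lack pairs at some
    separations; those lags are absent from the curve.
    """
    if traj.n_obs < 2:
        raise ValueError("MSD requires at least 2 observations")
    frames = traj.frames
    pos = traj.positions
    diff_f = frames[None, :] - frames[:, None]          # (i, j): f_j - f_i
    dpos = pos[None, :, :] - pos[:, None, :]
    # dx*dx + dy*dy (explicit products: bit-stable across scalar/vector paths)
    sq = dpos[..., 0] * dpos[..., 0] + dpos[..., 1] * dpos[..., 1]

    ks = np.unique(diff_f[diff_f > 0])
    lags = np.empty(ks.size)
    values = np.empty(ks.size)
    counts = np.empty(ks.size, dtype=np.int64)
    for idx, k in enumerate(ks):
        sel = diff_f == k
        lags[idx] = k * tau
        values[idx] = np.mean(sq[sel])
        counts[idx] = int(np.count_nonzero(sel))
    return MsdCurve(lags=lags, values=values, counts=counts)


def fit_power_law(msd: MsdCurve, window: tuple[float, float] = DEFAULT_FIT_WINDOW,
                  min_lags: int = 3, min_count: int = 2) -> PowerLawFit:
    """Unweighted least-squares fit of log MSD vs log lag inside ``window``.

    Lags averaged over fewer than ``min_count`` pairs are excluded as
    degenerate.  Raises :class:`FitFailure` when fewer than ``min_lags``
    usable lags remain or any in-window MSD is non-positive (the trajectory
    stays classifiable by its displacement rules only).
    """
    lo, hi = window
    eps = 1e-9
    in_window = (msd.lags >= lo - eps) & (msd.lags <= hi + eps)
    usable = in_window & (msd.counts >= min_count)
    if np.count_nonzero(usable) < min_lags:
        raise FitFailure(
            f"only {np.count_nonzero(usable)} usable lags in window {window}"
        )
    if np.any(msd.values[usable] <= 0):
        raise FitFailure("non-positive MSD value inside the fit window")
    log_t = np.log(msd.lags[usable])
    log_m = np.log(msd.values[usable])
    alpha, intercept = np.polyfit(log_t, log_m, 1)
    resid = log_m - (alpha * log_t + intercept)
    return PowerLawFit(
        D_a=float(np.exp(intercept) / 4.0),
        alpha=float(alpha),
        fit_window=(lo, hi),
        goodness=float(np.sqrt(np.sum(resid ** 2))),
        n_lags=int(np.count_nonzero(usable)),
    )


def try_fit_power_law(msd: MsdCurve, window: tuple[float, float] = DEFAULT_FIT_WINDOW,
                      **kwargs) -> PowerLawFit | None:
    """Like :func:`fit_power_law` but returns None on failure."""
    try:
        return fit_power_law(msd, window, **kwargs)
    except FitFailure:
        return None


def _frame_velocities(traj: Trajectory, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocities between consecutive observed frames.

    Returns (frames, v) where v[i] is the velocity vector over the interval
    starting at frames[i]; intervals spanning gaps contribute no velocity.
    """
    df = np.diff(traj.frames)
    sel = df == 1
    v = np.column_stack([np.diff(traj.x), np.diff(traj.y)])[sel] / tau
    return traj.frames[:-1][sel], v


def compute_vaf(traj: Trajectory, tau: float) -> VafCurve:
    """Velocity autocorrelation over frame-to-frame velocities.

    VAF(k*tau) averages v(t) . v(t + k*tau) over all times where both
    velocities exist (both defined on gap-free consecutive-frame intervals).
    An empty curve is returned when no velocity pair exists.
    """
    v_frames, v = _frame_velocities(traj, tau)
    if len(v) == 0:
        return VafCurve(np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))
    # dense frame-indexed layout (NaN where no velocity exists) so each lag
    # is a vectorized shifted product
    span = int(v_frames[-1] - v_frames[0]) + 1
    dense = np.full((span, 2), np.nan)
    dense[v_frames - v_frames[0]] = v
    lags, values, counts = [], [], []
    for k in range(0, span):
        a = dense[: span - k]
        b = dense[k:]
        dots = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
        valid = ~np.isnan(dots)
        n_valid = int(np.count_nonzero(valid))
        if n_valid:
            lags.append(k * tau)
            values.append(float(np.mean(dots[valid])))
            counts.append(n_valid)
    return VafCurve(np.array(lags), np.array(values), np.array(counts, dtype=np.int64))


def max_velocity(traj: Trajectory, tau: float) -> VelocityEstimate:
    """Maximum velocity from the correlation of successive velocities.

    For every pair of velocities on consecutive frames with a positive dot
    product, the speed estimate is sqrt(v(t) . v(t + tau)); the maximum over
    the trajectory is returned.  Requiring two consecutive fast steps with
    positive correlation suppresses single-frame localization-noise spikes.
    If no pair has a positive dot product, v_max = 0 with a flag set.
    """
    v_frames, v = _frame_velocities(traj, tau)
    if len(v) < 2:
        raise ValueError("max_velocity requires two consecutive velocity pairs")
    consecutive = np.diff(v_frames) == 1
    if not np.any(consecutive):
        raise ValueError("max_velocity requires two consecutive velocity pairs")
    dots = np.sum(v[:-1] * v[1:], axis=1)[consecutive]
    frames = v_frames[:-1][consecutive]
    positive = dots > 0
    if not np.any(positive):
        return VelocityEstimate(v_max=0.0, frame_of_max=int(frames[0]),
                                no_positive_correlation=True)
    best = int(np.argmax(np.where(positive, dots, -np.inf)))
    return VelocityEstimate(
        v_max=float(np.sqrt(dots[best])),
        frame_of_max=int(frames[best]),
        no_positive_correlation=False,
    )
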