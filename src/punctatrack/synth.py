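"""Synthetic trajectory and movie generation.

Generates labeled particle trajectories with the motion regimes the analysis
is designed to separate — immobile, free Brownian, confined Brownian,
directed, and switching (Brownian/directed two-state) — plus rendered movies,
so that every downstream stage can be validated against known ground truth.

Defaults emulate the acquisition the pipeline targets: 1 frame/s for 60
frames at ~0.2 um/pixel, with per-coordinate Gaussian localization error of
~14 nm, so a truly immobile particle shows an apparent step-size (Rayleigh)
scale of ~20 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MotionModel",
    "SimulationConfig",
    "LabeledTrajectorySet",
    "simulate_trajectory",
    "apply_dropout",
    "render_movie",
    "make_labeled_dataset",
    "KIND_TO_LABEL",
]

_KINDS = ("immobile", "brownian", "confined", "directed", "switching")

#: Ground-truth motion label implied by each generator kind.  Confined
#: particles are labeled brownian (they diffuse, just sub-diffusively);
#: switching particles contain stretches of transport and count as directed.
KIND_TO_LABEL = {
    "immobile": "immobile",
    "brownian": "brownian",
    "confined": "brownian",
    "directed": "directed",
    "switching": "directed",
}


@dataclass(frozen=True)
class MotionModel:
    """Parameters of one motion regime.

    D is the diffusion coefficient (um^2/s), v the transport speed (um/s)
    along ``heading`` (radians) for directed/switching motion, ``box_side``
    the side (um) of the reflecting confinement square, and ``switch_rates``
    the per-frame probabilities of toggling brownian->directed and
    directed->brownian for the switching model.  Parameters irrelevant to a
    kind are stored but ignored.
    """

    kind: str
    D: float = 0.0
    v: float = 0.0
    heading: float = 0.0
    box_side: float | None = None
    switch_rates: tuple[float, float] = (0.05, 0.05)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}; expected one of {_KINDS}")
        for name in ("D", "v"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        if self.kind == "immobile" and (self.D != 0 or self.v != 0):
            raise ValueError("immobile motion requires D = 0 and v = 0")
        if self.kind == "brownian" and self.v != 0:
            raise ValueError("brownian motion requires v = 0")
        if self.kind == "confined":
            if self.box_side is None or not np.isfinite(self.box_side) or self.box_side <= 0:
                raise ValueError("confined motion requires box_side > 0")
        if self.kind == "switching":
            for rate in self.switch_rates:
                if not 0 <= rate <= 1:
                    raise ValueError("switch_rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition-side parameters of a simulation.

    loc_noise_sigma is the per-coordinate localization error std in um; the
    default 0.014 um (= 20 nm / sqrt(2)) makes the apparent step-size scale
    of an immobile particle about 20 nm, the localization precision the
    mixture's first component estimates.
    """

    n_trajectories: int = 100
    n_frames: int = 60
    frame_interval: float = 1.0
    loc_noise_sigma: float = 0.014
    dropout_prob: float = 0.0
    intensity_mean: float = 100.0
    intensity_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.intensity_mean <= 0 or self.intensity_cv < 0:
            raise ValueError("intensity distribution must be positive")

    @property
    def tau(self) -> float:
        return self.frame_interval


@dataclass
class LabeledTrajectorySet:
    """Trajectories with their generation-time ground-truth motion labels."""

    trajectories: list[Trajectory]
    labels: list[str]
    config: SimulationConfig
    models: list[MotionModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.labels):
            raise ValueError("trajectories and labels must be parallel sequences")


def _reflect(positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold unconstrained coordinates into [lo, hi] by mirror reflection."""
    span = hi - lo
    folded = np.mod(positions - lo, 2 * span)
    folded = np.where(folded > span, 2 * span - folded, folded)
    return folded + lo


def _intensities(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    # lognormal parameterized by mean and coefficient of variation
    if config.intensity_cv == 0:
        return np.full(n, config.intensity_mean)
    sigma2 = np.log(1.0 + config.intensity_cv ** 2)
    mu = np.log(config.intensity_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def simulate_trajectory(model: MotionModel, config: SimulationConfig,
                        rng: np.random.Generator,
                        origin: tuple[float, float] = (0.0, 0.0),
                        traj_id: int = 0) -> Trajectory:
    """Simulate one trajectory under ``model``.

    Brownian increments are independent Gaussians per coordinate with
    variance 2*D*tau; directed motion advances v*tau along the heading on
    top of those increments; confined motion reflects the free path at a
    square box of side ``box_side`` centred on the origin; immobile particles
    keep a fixed true position.  Localization noise (std loc_noise_sigma) is
    added independently per frame and coordinate afterwards.
    """
    n = config.n_frames
    tau = config.tau
    step_sigma = np.sqrt(2.0 * model.D * tau)
    start = np.asarray(origin, dtype=float)

    if model.kind == "immobile":
        true = np.tile(start, (n, 1))
    elif model.kind in ("brownian", "confined", "directed"):
        increments = rng.normal(0.0, step_sigma, size=(n - 1, 2))
        if model.kind == "directed":
            drift = model.v * tau * np.array([np.cos(model.heading), np.sin(model.heading)])
            increments = increments + drift
        true = start + np.vstack([[0.0, 0.0], np.cumsum(increments, axis=0)])
        if model.kind == "confined":
            half = model.box_side / 2.0
            true = np.column_stack([
                _reflect(true[:, 0], start[0] - half, start[0] + half),
                _reflect(true[:, 1], start[1] - half, start[1] + half),
            ])
    elif model.kind == "switching":
        drift = model.v * tau * np.array([np.cos(model.heading), np.sin(model.heading)])
        p_on, p_off = model.switch_rates
        true = np.empty((n, 2))
        true[0] = start
        directed_state = False
        for i in range(1, n):
            toggle_p = p_off if directed_state else p_on
            if rng.random() < toggle_p:
                directed_state = not directed_state
            step = rng.normal(0.0, step_sigma, size=2)
            if directed_state:
                step = step + drift
            true[i] = true[i - 1] + step
    else:  # pragma: no cover - guarded by MotionModel validation
        raise ValueError(model.kind)

    observed = true + rng.normal(0.0, config.loc_noise_sigma, size=true.shape)
    return Trajectory(
        id=traj_id,
        frames=np.arange(n, dtype=np.int64),
        x=observed[:, 0],
        y=observed[:, 1],
        intensity=_intensities(n, config, rng),
    )


def apply_dropout(traj: Trajectory, dropout_prob: float,
                  rng: np.random.Generator) -> Trajectory:
    """Remove interior observations independently with ``dropout_prob``.

    First and last observations are always retained, so trajectory duration
    is unchanged; surviving frame indices keep their original values (the
    result has explicit gaps).
    """
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must lie in [0, 1)")
    if dropout_prob == 0 or traj.n_obs <= 2:
        return traj
    keep = rng.random(traj.n_obs) >= dropout_prob
    keep[0] = keep[-1] = True
    return Trajectory(traj.id, traj.frames[keep], traj.x[keep], traj.y[keep],
                      traj.intensity[keep])


def render_movie(traj_set: Sequence[Trajectory], pixel_size: float,
                 image_shape: tuple[int, int], psf_sigma: float,
                 background: float, rng: np.random.Generator,
                 n_frames: int | None = None,
                 poisson_noise: bool = True) -> np.ndarray:
    """Render trajectories as a (frames, H, W) image stack.

    Each visible particle contributes an isotropic 2D Gaussian spot (std
    ``psf_sigma`` pixels) whose integrated intensity equals the particle's
    intensity for that frame, on a uniform ``background``; Poisson shot
    noise is applied to the expected photon image unless disabled.
    Trajectory positions (um) are mapped to pixels via ``pixel_size``.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    h, w = image_shape
    if n_frames is None:
        n_frames = 1 + max((int(t.frames[-1]) for t in traj_set), default=0)
    expected = np.full((n_frames, h, w), float(background))

    half = int(np.ceil(4 * psf_sigma))
    for traj in traj_set:
        for frame, x_um, y_um, inten in zip(traj.frames, traj.x, traj.y, traj.intensity):
            cx = x_um / pixel_size
            cy = y_um / pixel_size
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(
                    f"particle {traj.id} is outside the field in frame {int(frame)}: "
                    f"({cx:.1f}, {cy:.1f}) px for shape {(h, w)}"
                )
            r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            r0, r1 = max(r0, 0), min(r1, h)
            c0, c1 = max(c0, 0), min(c1, w)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            spot = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf_sigma ** 2))
            spot *= inten / (2 * np.pi * psf_sigma ** 2)
            expected[int(frame), r0:r1, c0:c1] += spot

    if poisson_noise:
        return rng.poisson(expected).astype(float)
    return expected


def make_labeled_dataset(config: SimulationConfig,
                         class_mix: Mapping[str, float],
                         model_params: Mapping[str, MotionModel] | None = None,
                         rng: np.random.Generator | None = None,
                         origin_box: float = 0.0) -> LabeledTrajectorySet:
    """Generate ``config.n_trajectories`` trajectories with ground-truth labels.

    ``class_mix`` maps motion kinds to fractions summing to 1; allocation is
    deterministic (largest-remainder rounding), so the per-class counts are a
    fixed function of the mix and the total.  ``model_params`` overrides the
    default motion parameters per kind.  With ``origin_box`` > 0, starting
    positions are scattered uniformly over that square (um), as needed for
    movie rendering; otherwise all trajectories start at the origin.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if not class_mix:
        raise ValueError("class_mix must name at least one motion kind")
    total_frac = float(sum(class_mix.values()))
    if not np.isclose(total_frac, 1.0):
        raise ValueError(f"class_mix fractions must sum to 1, got {total_frac}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    defaults = {
        "immobile": MotionModel("immobile"),
        "brownian": MotionModel("brownian", D=5e-3),
        "confined": MotionModel("confined", D=5e-3, box_side=0.3),
        "directed": MotionModel("directed", v=0.2),
        "switching": MotionModel("switching", D=2e-3, v=0.2),
    }
    if model_params:
        defaults.update(model_params)

    kinds = sorted(class_mix)
    n_total = config.n_trajectories
    raw = {k: class_mix[k] * n_total for k in kinds}
    counts = {k: int(np.floor(raw[k])) for k in kinds}
    remainder = n_total - sum(counts.values())
    for k in sorted(kinds, key=lambda k: (-(raw[k] - counts[k]), k))[:remainder]:
        counts[k] += 1

    trajectories: list[Trajectory] = []
    labels: list[str] = []
    models: list[MotionModel] = []
    traj_id = 0
    for kind in kinds:
        model = defaults[kind]
        if model.kind != kind:
            raise ValueError(f"model_params[{kind!r}] has kind {model.kind!r}")
        for _ in range(counts[kind]):
            if origin_box > 0:
                origin = tuple(rng.uniform(0.0, origin_box, size=2))
            else:
                origin = (0.0, 0.0)
            if kind in ("directed", "switching"):
                model_i = replace(model, heading=rng.uniform(0, 2 * np.pi))
            else:
                model_i = model
            traj = simulate_trajectory(model_i, config, rng, origin=origin,
                                       traj_id=traj_id)
            if config.dropout_prob > 0:
                traj = apply_dropout(traj, config.dropout_prob, rng)
            trajectories.append(traj)
            labels.append(KIND_TO_LABEL[kind])
            models.append(model_i)
            traj_id += 1

    return LabeledTrajectorySet(trajectories, labels, config, models)
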