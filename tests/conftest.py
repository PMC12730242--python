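import numpy as np
import pytest

from punctatrack import (MotionModel, SimulationConfig, Trajectory,
                         compute_geometry, make_labeled_dataset)


@pytest.fixture
def geometry():
    """0.2 um/px, 1 s frame interval (the canonical acquisition)."""
    return compute_geometry(L=102.4, N=512, T=60.0, F=61)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_gapped_trajectory(rng, traj_id=0, max_obs=40):
    """A random trajectory with random gaps, for oracle comparisons."""
    n = rng.integers(3, max_obs)
    frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False))
    return Trajectory(
        id=traj_id,
        frames=frames,
        x=rng.normal(0, 1, n),
        y=rng.normal(0, 1, n),
        intensity=rng.uniform(50, 150, n),
    )


@pytest.fixture
def labeled_benchmark():
    """The seeded 3-class benchmark: 200 trajectories per class at 60 frames
    (immobile: localization noise only; Brownian D=4e-3 um^2/s; directed
    v=0.2 um/s)."""
    cfg = SimulationConfig(n_trajectories=600, n_frames=60,
                           loc_noise_sigma=0.014, seed=42)
    mix = {"immobile": 1 / 3, "brownian": 1 / 3, "directed": 1 / 3}
    models = {"brownian": MotionModel("brownian", D=4e-3),
              "directed": MotionModel("directed", v=0.2)}
    return make_labeled_dataset(cfg, mix, models)
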