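# punctatrack

Single-particle tracking and motion classification for intracellular
fluorescent puncta.

Fluorescently tagged proteins (for example bacterial magnetosome proteins
expressed in mammalian cells) often assemble into diffraction-limited
punctate structures whose intracellular mobility carries biological
information: are the particles stuck, diffusing inside a crowded cytoplasm,
or hauled along the cytoskeleton by molecular motors?  `punctatrack` turns
single-channel time-lapse confocal movies (typically 1 frame/s for 60 s at
~0.2 µm/pixel) into per-trajectory motion metrics, per-cell summaries, and
condition-level comparisons, and ships a synthetic-data generator so every
stage can be validated against known ground truth.

## The model

**MSD power law.**  For each trajectory the time-averaged mean-squared
displacement is fitted over lag times 1–10 s with

    ⟨r²(t)⟩ = 4 D_a t^α

where α ≈ 1 indicates free Brownian motion, α < 1 constrained diffusion,
and α ≈ 2 directed transport.  D_a is an *apparent* diffusion coefficient
(for α ≠ 1 it is the diffusivity implied by the MSD at t = 1 s).

**Step-size mixture.**  All single-frame displacements of a cell's accepted
trajectories are pooled and fitted by maximum likelihood with a
two-component Rayleigh mixture,

    p(r) = f₁ (r/s₁²) e^(−r²/2s₁²) + f₂ (r/s₂²) e^(−r²/2s₂²),

where each scale maps to a diffusion coefficient via sᵢ = √(2 Dᵢ τ).  The
small scale s₁ is the apparent step of immobile particles — i.e. the
localization precision (~20 nm) — and s₂ is the diffusive step scale.  A
zero-truncated Gaussian third component is added automatically when a
distinct population of longer, transport-like steps improves the BIC.

**Classification.**  Each trajectory with n steps is labeled:

- *immobile* if its net displacement **and** largest step are both < 12·s₁;
- *directed* if its net displacement exceeds 1.5·s₂·√n, or its fitted
  α > 1.1;
- *brownian* otherwise.

Per-cell summaries report class percentages, D_a and α over the Brownian
subset, and the maximum velocity v_max (from the correlation of successive
frame-to-frame velocities, Eq. √(v(t)·v(t+τ))) over the directed subset.
Conditions are compared with one-way ANOVA plus Tukey's HSD.

## Worked example

```python
import numpy as np
from punctatrack import (MotionModel, SimulationConfig, compute_geometry,
                         make_labeled_dataset, analyze_cell)

geometry = compute_geometry(L=102.4, N=512, T=59.0, F=60)   # 0.2 um/px, 1 s
config = SimulationConfig(n_trajectories=300, n_frames=60, seed=7)
dataset = make_labeled_dataset(
    config,
    class_mix={"immobile": 0.25, "brownian": 0.50, "directed": 0.25},
    model_params={"brownian": MotionModel("brownian", D=4e-3),
                  "directed": MotionModel("directed", v=0.2)},
)

result = analyze_cell(dataset.trajectories, geometry, cell_id="demo")
fit = result.mixture
print(f"accepted {len(result.qc.accepted)}/{result.qc.n_input} trajectories")
print(f"s1 = {fit.s1*1e3:.0f} nm  (localization precision)")
print(f"s2 = {fit.s2*1e3:.0f} nm  (diffusive step scale, D2 = {fit.D2:.2e} um^2/s)")
if fit.gaussian:
    print(f"directed step peak at {fit.gaussian.mu:.2f} um ({100*fit.gaussian.f:.0f}% of steps)")
s = result.summary
print(f"immobile {s.pct_immobile:.1f}%  brownian {s.pct_brownian:.1f}%  directed {s.pct_directed:.1f}%")
print(f"Brownian subset: D_a = {s.D_a_mean:.2e} +/- {s.D_a_sd:.1e} um^2/s, alpha = {s.alpha_mean:.2f}")
print(f"directed subset: v_max = {s.v_max_mean:.2f} +/- {s.v_max_sd:.2f} um/s")
```

prints

```
accepted 257/300 trajectories
s1 = 20 nm  (localization precision)
s2 = 92 nm  (diffusive step scale, D2 = 4.20e-03 um^2/s)
directed step peak at 0.20 um (25% of steps)
immobile 26.5%  brownian 30.0%  directed 43.6%
Brownian subset: D_a = 4.34e-03 +/- 6.8e-04 um^2/s, alpha = 0.90
directed subset: v_max = 0.21 +/- 0.03 um/s
```

The quality filter drops dim and short tracks; the mixture recovers the
20 nm localization floor, the true Brownian step scale (D₂ ≈ 4×10⁻³ µm²/s)
and the 0.2 µm directed step peak; and v_max matches the simulated transport
speed.  Free Brownian trajectories are the hard boundary of the
displacement-based directed rule — a genuinely free random walk exceeds
1.5·s₂·√n with probability exp(−1.125) ≈ 0.32 — so part of the Brownian
population is promoted to "directed", which is why the directed fraction
exceeds the simulated 25% (see `docs/methods.md`).

## Command line

```sh
punctatrack simulate --out sim --n 200 --mix "immobile=0.3,brownian=0.5,directed=0.2" --seed 1
punctatrack track    --stack movie.tif --config cfg.yaml --out tracks.csv
punctatrack analyze  --traj sim/trajectories.csv --out analysis --seed 1
punctatrack report   --cells cells_with_condition.csv --out report
```

Every output embeds the configuration hash; identical config + seed
reproduce all outputs byte for byte.

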