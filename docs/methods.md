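# Methods

This note records the models implemented in `punctatrack`, the parameter
choices that matter, and the limits of what the synthetic benchmarks can
show about real data.

## Acquisition geometry

A movie is described by the field width L (µm), pixel count N, total
duration T (s) and frame count F, from which the pixel width d = L/N and
frame interval τ = T/(F − 1) follow.  The defaults (L = 102.4 µm, N = 512,
T = 60 s, F = 61) give the canonical 0.2 µm/px at 1 frame/s.  All analysis
is done in micrometres and seconds; pixel coordinates are 0-based with the
origin at the top-left pixel centre, x rightward and y downward, and are
converted once, at linking or table-reading time.

## Detection and linking

Candidate spots are local maxima (within the particle `radius`) whose value
lies in the top `percentile` of the frame's intensity range; each candidate
is refined to a background-subtracted intensity-weighted centroid over the
disc of that radius, and its summed disc intensity must exceed `cutoff`.
Refined detections closer than one radius are merged keeping the brighter.
On rendered spots with SNR ≥ 10 the centroid is accurate to < 0.2 px RMS.
`percentile` and `cutoff` are per-movie tunables, as they would be set by an
operator balancing manifest particles against noise speckle; the defaults
are deliberately conservative (top 1 % of the range).

Linking is greedy nearest-neighbour: candidate (track, detection) pairs
within `max_disp` pixels (default 10) are assigned in order of ascending
distance, ties broken by lower track id for determinism.  A track missing
from up to `link_range − 1` consecutive frames can be gap-closed; after
`link_range` (default 3) consecutive absent frames it is terminated.  Gaps
are never interpolated — downstream statistics skip them explicitly.  This
is intentionally not a multi-hypothesis/LAP tracker; with well-separated
particles (spacing > 2·`max_disp`) it recovers ground truth exactly, which
is the regime the quality filter retains anyway.

## Quality control

A trajectory is rejected if any of the following fires (first failure
recorded): fewer than 8 observed frames; a consecutive-frame displacement
above 1 µm; a displacement across a one-frame gap above 3 px; mean
intensity more than 1 SD below the population mean; or detections covering
less than 70 % of the trajectory duration.  The displacement limits are
configuration, not code — in practice they are adjusted per cell with the
imaging parameters.  "Fewer than 8 frames" counts observed frames, not
duration, and the intensity population statistics are computed once, over
the per-trajectory mean intensities of all input trajectories, before any
rejection; a report can carry those statistics forward so re-filtering the
accepted set is a no-op.  Note the intensity rule always trims the dim tail
of the population (about 16 % under the synthetic lognormal intensity
model); it is a relative filter, not an absolute one.

## Per-trajectory metrics

The MSD is time-averaged over all ordered observation pairs separated by
exactly k frames; lags with no pairs are simply absent.  The power law
⟨r²(t)⟩ = 4 D_a t^α is fitted unweighted in log–log space over lag times
1–10 s; lags averaged over fewer than 2 pairs are dropped as degenerate, and
fewer than 3 usable lags (or a non-positive in-window MSD) is a fit failure
— the trajectory then remains classifiable by its displacement rules alone.
Log–log least squares was chosen because it linearizes the model and is
robust on 10-point windows; squared distances are accumulated with explicit
products so the estimator is bit-reproducible against a brute-force oracle.

The velocity autocorrelation ⟨v(0)·v(t)⟩ uses frame-to-frame velocities
defined only on gap-free intervals; it is computed and reported as a
persistence diagnostic but is not a classification input.  The maximum
velocity is max over t of √(v(t)·v(t+τ)) over consecutive velocity pairs
with positive dot product (none positive ⇒ v_max = 0, flagged).  Requiring
two consecutive correlated fast steps suppresses single-frame localization
spikes, but taking a maximum over ~57 noisy correlations still biases the
estimate upward at low speeds: with 20 nm-scale noise the bias is ≈ +22 %
at 0.1 µm/s, +11 % at 0.2 µm/s and +7 % at 0.3 µm/s.  This is a property of
the estimator itself and should be kept in mind when comparing slow
transport speeds.

## Step-size mixture

Consecutive-frame step magnitudes pooled per cell are fitted by
expectation–maximization with closed-form Rayleigh scale updates
(s_j² = Σ γ_ij r_i² / 2 Σ γ_ij).  Initialization is deterministic — s₁ at
the 20 nm localization prior, s₂ at the RMS step — so fits are reproducible
without randomized restarts; components are reported sorted by scale.
Maximum likelihood on the raw steps avoids histogram bin-width sensitivity.
Fewer than 50 steps falls back to a single Rayleigh with a warning.  Steps
of exactly zero carry no Rayleigh likelihood and are excluded.

The optional third component for directed steps is a Gaussian truncated at
zero (renormalized on r ≥ 0, so the mixture always integrates to 1); its
M-step uses weighted moments, exact in the µ ≫ σ regime where the component
is meaningful.  In `auto` mode the third component is kept only if the BIC
improves over the two-component fit *and* its peak lies beyond the
diffusive scale (µ > s₂).  A tail-mass trigger (excess data beyond the
two-component fit's 0.999 quantile) was evaluated and rejected: the
two-component EM absorbs any directed peak into the second Rayleigh, so the
observed tail mass beyond the fit's own extreme quantile stays near the
nominal 0.1 % and such a trigger essentially never fires.  The BIC rule
recovers planted directed peaks down to ~3 % of steps while leaving clean
two-component data untouched.

## Classification

With s₁ and s₂ from the cell's mixture fit, each trajectory with n steps is
labeled by fixed-order rules: immobile if net start-to-end displacement and
largest consecutive-frame step are both < 12·s₁ (the particle stays inside
one diffraction-limited area, ~240 nm, with headroom for slow whole-cell
drift); else directed if net displacement > 1.5·s₂·√n (a diffusing
particle's expected excursion is s₂·√n) or fitted α > 1.1; else brownian.
"Total displacement" is net excursion, not path length — the immobile
rationale concerns whether the particle leaves its starting neighbourhood.
The immobile test precedes the directed test so a tightly confined track
with a spurious α cannot be promoted.  α from failed or unconverged fits is
not used; such trajectories are decided by the displacement rules alone,
and the deciding rule is recorded per trajectory.

A quantitative caveat the synthetic benchmark makes explicit: for *free*
Brownian motion the net displacement after n steps is Rayleigh-distributed
with scale s₂√n, so the directed rule fires spuriously with probability
exp(−1.5²/2) ≈ 0.325 even when s₂ is estimated perfectly, and the α > 1.1
branch adds further false promotions.  On the labeled benchmark (200
trajectories per class, 60 frames; immobile with 20 nm noise, Brownian
D = 4×10⁻³ µm²/s, directed v = 0.2 µm/s) recall is 1.0 for immobile and
directed but only ≈ 0.55 for free Brownian, with essentially all misreads
promoted to directed.  The thresholds are effective when diffusing
particles are subdiffusive (α ~ 0.4–0.5), as intracellular vesicles
typically are — confined walks rarely reach 1.5·s₂·√n — but percentages of
"directed" trajectories should be read as upper bounds wherever genuinely
free diffusion is plausible.

## Summaries and statistics

Cell summaries report class percentages (one decimal; rounding means rows
need not sum to exactly 100), D_a and α over Brownian-labeled trajectories,
and v_max over directed-labeled trajectories.  Condition aggregation is the
unweighted across-cell mean ± SD with trajectory counts summed; a
single-cell condition reports SD 0 with a flag.  Conditions are compared
per metric with one-way ANOVA and Tukey's HSD (scipy's studentized-range
implementation, cross-checked against statsmodels); identical groups take
the degenerate F = 0, p = 1 path explicitly.

## Synthetic data

The generator emulates the target acquisition: 60 frames at τ = 1 s,
per-coordinate Gaussian localization error of 0.014 µm (= 20/√2 nm, so an
immobile particle's apparent step scale is 20 nm), lognormal intensities
(mean 100, CV 0.2), and optional per-frame dropout that never removes
trajectory endpoints.  Motion regimes: immobile; free Brownian with
per-coordinate increment variance 2Dτ; confined Brownian reflected at a
square box (reflection is the simplest mechanism producing α < 1 at long
lags; the stationary positional variance is bounded by side²/12 per
coordinate); directed transport v·τ along a fixed heading on top of
Brownian increments; and a two-state Markov switcher between Brownian and
directed phases (default toggle probability 0.05/frame each way).  Default
parameter ranges (D = 10⁻³–10⁻² µm²/s, v = 0.1–0.3 µm/s, sub-µm
confinement) bracket the mobility regime of intracellular vesicle cargo;
they are a test harness, not an assertion about any particular biological
system.  Movies are rendered as isotropic Gaussian spots (integrated
intensity = particle intensity) on a uniform background with Poisson shot
noise.  Not emulated: photobleaching, motion out of the focal plane, camera
gain and read noise, anisotropic PSFs, spatially varying background, and
particle collisions/crossings at realistic densities — so passing tests
validate the estimators and the pipeline plumbing, not detection/linking
performance in crowded, low-SNR cells.

## Problem sizes and numerical choices

The validation suite uses desk-scale ensembles chosen to make sampling
error small relative to the asserted tolerances: 10⁵ steps for increment
statistics, 1000/500 trajectories for the free/confined exponent ensembles,
10⁴ steps × 20 seeds for mixture recovery, and 200 trajectories per class
for the classifier benchmark.  EM convergence is declared when the
log-likelihood gain drops below 10⁻¹⁰ relative (500 iterations max,
non-convergence flagged, best parameters kept); Rayleigh scales are floored
at 10⁻⁶ µm against degenerate collapse; assignment ties in linking are
broken by track id; all simulations take explicit seeds and identical
config + seed reproduces every output byte for byte.
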