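# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind each pipeline stage, and what the passing test suite
does and does not establish about real recordings.

## Oculomotor gain and phase

Cyclic gaze-stabilization trials are modeled as a sinusoidal positional
stimulus `A sin(2πft)` (defaults: f = 0.5 Hz, A = 10° for vestibular
rotation; f = 0.1 Hz, A = 10° for optokinetic pattern motion) and an eye
response at gain g and phase φ. The sign conventions are:

- φ is in degrees relative to peak stimulus position, in (−180°, 180°],
  **negative = lead**;
- vestibular responses are compensatory (anti-phase), and are
  sign-reflected before peak comparison so a perfect compensatory response
  scores φ = 0. The reflection is exposed (`reflect_vestibular`) because
  the raw anti-phase convention is also in use.

Processing: linear-interpolation resampling to 200 Hz; 4th-order
Butterworth low-pass at 4 Hz applied forward–backward (`filtfilt`), so the
filter contributes no phase shift to the metric it feeds; conjugate
averaging of the two eyes; segmentation into stimulus cycles between
successive stimulus maxima; pointwise averaging of non-excluded cycles on
a common 200-point cycle-phase grid.

Gain is peak-to-peak eye / peak-to-peak stimulus of the averaged cycle.
Phase is 360° times the cycle-fraction offset between the eye and stimulus
peaks. Peak position is localized by a least-squares parabola over ±10% of
the cycle around the discrete maximum: a plain 3-point parabola quantizes
poorly at shallow peaks (a 0.05-gain response with 0.5° noise can move the
3-point peak by >3°), while the windowed fit keeps fixed-seed phase errors
under ~2° at the lowest published gain.

Fast-phase exclusion: a cycle is dropped when its peak eye velocity
exceeds `jerk_factor` (default 5) times a reference slow-phase velocity,
taken as the median per-cycle peak eye velocity capped at the velocity a
stimulus-following response of gain 1.5 could produce. The median
self-calibrates across gains and noise levels; the cap guards against a
fast-phase-dominated median. Manually identified cycle indices can be
excluded as well.

Circular statistics: the mean vector of per-animal phases gives the mean
direction and vector strength r ∈ [0, 1]; group differences use the
Watson–Williams F-test with the standard 1 + 3/(8κ̂) correction (κ̂ from
the mean resultant length). The test warns below r̄ = 0.45 where the
von-Mises approximation degrades; under a concentrated null its measured
type-I error at α = 0.05 is 0.05 ± 0.01 (1000-replicate simulation in the
test suite).

## Swim kinematics and bout detection

From six landmarks (eyes, skull centre, body centre of mass, two tail
points; image-convention pixel coordinates at 30 frames/s, converted to mm
by the pixel scale):

- swim speed = per-frame displacement of the centre of mass × frame rate;
- tail angle = angle between the skull→COM axis and the COM→tail1 axis
  (tail2 selectable);
- head angle = inter-eye line vs the image horizontal, differentiated
  twice for angular acceleration using a five-point (fourth-order) central
  stencil — the twice-applied two-point gradient attenuates a 2 Hz yaw at
  30 frames/s by ~6%, the five-point stencil by <0.1%.

Speed and tail-velocity traces are Savitzky–Golay smoothed (window 15,
order 3). Bout detection declares a frame active when smoothed speed
> 3 mm/s AND the smoothed **rectified** tail-velocity envelope > 3 °/s.
Rectifying before smoothing matters: the signed velocity of any tail
oscillation crosses zero twice per beat, so thresholding its magnitude
would cut a one-frame hole into a bout whenever a video frame lands near a
reversal. For the same reason sub-threshold gaps of ≤2 frames are closed
before runs become bouts. Both thresholds are strict inequalities and the
conjunction is evaluated per frame, discarding tail-only motion and
passive drift. Bout summaries weight each bout duration by itself (a 30 s
bout contributes 30× a 1 s bout) before normalizing to a unit-integral
probability density. Distribution comparisons use the two-sample
Kolmogorov–Smirnov statistic (asymptotic two-sided p), verified in the
tests against a brute-force empirical-CDF supremum.

## Canal morphometry

All 3D work is in micrometres, voxel order (z, y, x), converted on load.

- **Segmentation**: Gaussian blur (default σ = 4 voxels), Otsu or fixed
  threshold, largest connected component.
- **2D circuit**: direct least-squares ellipse fit (Halíř–Flusser, via
  scikit-image) to boundary or centerline-projection points; circuit
  radius R is the root mean square of the semi-axes,
  `R = sqrt((Ra² + Rb²)/2)`, which reduces to the radius for a circle.
  The ampulla ratio (major/minor, 1 = perfect circle) uses the same fit.
- **Ellipsoid descriptors**: semi-axes from the second moments of the
  foreground voxel cloud (`axis = sqrt(5·eigenvalue)`, exact for a solid
  ellipsoid), ordered a ≥ b ≥ c; elongation a/b, flatness b/c. Because
  moment eigenvalues are invariant under rigid rotation, a tilted copy of
  a planar canal scores identically in this mode; the alternative
  `c_mode="zext"` reads the depth axis as half the anatomical z-extent,
  which is the reading under which out-of-plane tilt lowers flatness.
  Both modes are tested.
- **Centerline**: 3D skeletonization, 26-connected graph, geodesically
  longest endpoint-to-endpoint path (side spurs trigger a warning, closed
  loops an error), moving-average smoothing (window 5). The medial axis
  retracts about one tube radius from each duct end; the path is therefore
  extended along its end tangents to the farthest foreground voxel inside
  a thin coaxial cylinder (half a tube radius wide), which recovers the
  retracted length without drifting off-axis on curved ducts. Duct length
  is the polyline arc length; on phantoms it is accurate to ~2%.
- **Cross-section profile**: at ~1-voxel arclength steps the plane
  perpendicular to the local tangent is sampled at half-voxel pitch; the
  area is the in-plane connected component containing the centerline
  point. The outermost half tube radius at each end is not profiled (a
  perpendicular plane there only grazes the end cap). The profile is
  interpolated to 200 arclength samples and oriented with the wider
  (ampulla) end at arclength 1. A stenosis is reported when the minimum
  within the ampulla-proximal third falls below mean − 1 SD of the profile
  and below half the mean; the min/mean ratio and argmin position are
  always reported.
- **Sensitivity**: `X_max = Cst·R·r²` with Cst ≡ 1 — the constant bundles
  endolymph properties that are unknown here, so only relative
  sensitivities (between species or stages) are meaningful. `xmax_grid`
  provides iso-sensitivity surfaces over an (r, R) grid.

## Spino-ocular coupling

Tail cycles are delimited by successive upward zero crossings of the
mean-subtracted tail angle (trace edges close a cycle when they lie a full
median period from the nearest crossing); cycles under 2° peak-to-peak are
ignored as noise. A cycle is "matched" when the eye trace within it
exceeds 0.5° peak-to-peak and co-varies negatively with the tail — the
covariance sign operationalizes "opposite direction", which is otherwise a
qualitative description. The eye/tail cycle ratio is the matched
percentage; the per-cycle gain (eye amplitude / tail amplitude) is binned
by tail amplitude (5° bins) and summarized by an ordinary least-squares
slope. Both noise floors are configurable; the estimator is unbiased on
the paired-trace generator (mean error <0.1 percentage points over 100
seeds).

## Cross-cohort resampling PCA

Different measures come from different animal cohorts, so feature vectors
have missing entries. Each missing cell is drawn with replacement from the
observed values of that variable within the same species — the most
conservative completion, treating variables as independent within-species
draws; species-restricted donor pools are the default (a cross-species
pool is available) because cross-species pooling would blur exactly the
between-species structure the analysis quantifies. Each completed
replicate is z-scored per variable with its own statistics (a
whole-cohort-normalization switch is not provided; with no missing data
the two coincide). PCA runs per replicate; components are sign-aligned
(largest-magnitude loading positive — averaging is ill-defined without a
sign rule), averaged loading-wise, re-orthonormalized by Gram–Schmidt in
component order, and averaged variance fractions are attached. The
representative dataset minimizes the elementwise sum of squared
differences to the replicate mean (ties to the lowest index). Scores are
plain dot products of the normalized data with the averaged components;
the loading map scales each component by its variance fraction, retaining
signs. Cross-section shape features are the first five PCA scores of the
length-normalized, mean-centered area profiles.

A consequence of per-variable z-scoring worth noting: a two-point species
mixture with raw gap d has z-space separation d/sqrt(1 + d²/4) < 2, so
arbitrarily large raw effects saturate and the loading order among strong
species markers is driven by their relative (not absolute) effects.

## Synthetic data: what it emulates and what it does not

Generators are deterministic given a seed and always return their ground
truth. Defaults encode the study conditions they stand in for:

- **Swim trajectories** (30 frames/s, 0.1 mm/px, 60 s): scripted bouts at
  5 mm/s with 4 Hz tail beats (±15°) and eye-line yaw. The `xenopus_54`
  preset scripts equal bouts totalling 28.8 s per 60 s; `axolotl_54`
  scripts 12 bouts of 0.89 s totalling 10.7 s with passive glides
  (exponential speed decay, τ = 0.05 s — fast enough that the glide drops
  below the 3 mm/s detection floor within ~1.5 frames, making the
  scheduled bouts themselves the detectable ground truth; the published
  bout statistics are detected quantities, so a generator whose glide
  lingered above threshold would build a bias into every recovery test).
  Tracker jitter is temporally correlated (Gaussian kernel, σ = 4 frames)
  with 3 μm amplitude: a marker on a still animal wanders slowly rather
  than flickering. This is deliberately at the clean end of pose-tracker
  behaviour — the published 3 °/s tail threshold is only meaningful when
  frame-to-frame angle noise sits well below it, and with iid jitter at
  typical tracker amplitudes it would not be. Passing tests therefore
  show the estimators are correct on smooth traces, not that raw tracker
  output can be thresholded without pre-filtering.
- **Eye traces** (200 samples/s): stimulus `A sin(2πft)`, slow-phase
  response `g·A·sin(2πft − φ_rad)` (negated for vestibular conditions),
  optional white noise, optional resetting fast phases as 100 ms linear
  position steps opposite to the ongoing slow-phase direction (their
  amplitude defaults to 4 g A or 5°, whichever is larger). Real fast
  phases have richer dynamics; only their exclusion is modeled.
- **Eye–tail traces** (250 samples/s, 2.5 Hz tail): exactly
  `round(fraction·n)` randomly placed tail cycles carry an anti-phase eye
  cycle; per-cycle amplitude jitter and a linear gain-amplitude slope are
  available for slope-recovery tests.
- **Canal phantoms**: elliptic-torus segments with constant tube radius
  modulated by a Gaussian ampulla bulge (15% of arc at one end) and an
  optional Gaussian stenosis; flat end caps; optional Gaussian-blurred
  grayscale with additive noise. No optics/PSF model beyond the blur, no
  real lumen wall texture.
- **Cohorts**: two species × n animals over Gaussian variables, a graded
  species offset on a subset (full effect on the first, a configurable
  fraction on the rest), missing cells blanked at random with every
  variable kept observed at least once per species.

## Problem sizes and determinism

The test suite and the acceptance script regenerate everything at run
time; the largest objects are canal phantoms of ~6·10⁶ voxels (3 μm,
duct-length recovery) and ~1.8·10⁷ voxels (2 μm, lumen-radius recovery),
chosen as the coarsest grids at which the published radii are recoverable
within their 3–5% tolerances. The full suite runs in under two minutes on
one CPU; the acceptance script in under one. All randomness flows through
`numpy.random.default_rng` seeded per run.

## Known limitations

- Bout-edge localization is accurate to ~2 frames at 30 frames/s; bouts
  shorter than ~0.2 s are at the resolution limit of the smoothing window.
- The cross-section area at a given arclength uses a single perpendicular
  plane; strongly non-circular or branching lumina would need an
  integral-geometry treatment.
- The Watson–Williams test assumes concentrated, equal-concentration von
  Mises samples; it is a poor tool for dispersed phase data (r̄ < 0.45).
- Imputation treats variables as independent within species; correlations
  between measures within an animal are not preserved, which is
  conservative for detecting cross-variable structure.
- Moment-based ellipsoid descriptors are orientation-invariant; use
  `c_mode="zext"` when the anatomical vertical is the relevant axis.
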