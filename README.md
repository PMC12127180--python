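# otokin

Quantitative tools linking inner-ear geometry to gaze stabilization and
locomotion in larval amphibians — an analysis pipeline for the kind of
comparative study that asks why one species (the axolotl, a thrust-and-glide
sit-and-wait predator) stabilizes gaze so much worse than another (the
continuously swimming *Xenopus* tadpole), and how much of that difference is
already written into the shape of the horizontal semicircular canal.

The package covers four measurement domains and one integration step:

- **oculomotor** — gain and phase of the angular vestibulo-ocular reflex
  (aVOR, in dark or light) and the optokinetic reflex (OKR) from paired
  stimulus/eye position traces: resampling to 200 Hz, zero-lag 4 Hz low-pass
  Butterworth filtering, conjugate eye averaging, peak-to-peak cycle
  segmentation with fast-phase exclusion, cycle averaging. Gain is the
  peak-to-peak eye excursion over the peak-to-peak stimulus excursion; phase
  is the cycle offset of the response peak in degrees, negative = lead.
  Circular statistics (mean vector, vector strength *r*, Watson–Williams F)
  summarize phases across animals.
- **swim_kinematics** — swim speed, path, tail-deflection velocity and head
  angular acceleration from six pose-tracked landmarks at 30 frames/s
  (Savitzky–Golay smoothing, window 15, order 3); bout detection as maximal
  runs where speed > 3 mm/s AND tail-deflection speed > 3 °/s;
  duration-weighted bout-length densities; two-sample Kolmogorov–Smirnov
  comparisons.
- **canal_morphometry** — from a segmented 3D canal volume: circuit radius
  R = sqrt((Ra² + Rb²)/2) of the fitted duct-circuit ellipse, lumen radius
  r = sqrt(cs_mean/π), moment-equivalent ellipsoid with elongation (a/b) and
  flatness (b/c), skeleton-based duct centerline and length, cross-section
  area profile with stenosis metrics, and the endolymph-displacement
  sensitivity proxy **X_max = Cst · R · r²**.
- **spino_ocular** — efference-copy driven eye movements during head-fixed
  swimming: tail-cycle detection by zero crossings, anti-phase eye matching
  per cycle, the eye/tail cycle ratio (%), and spino-ocular gain vs tail
  amplitude.
- **cohort_pca** — integration of all measures across cohorts with missing
  entries: within-species resampling imputation repeated (10,000× by
  default), per-replicate z-scoring and PCA, sign-aligned component
  averaging, most-representative replicate selection, projections and
  variance-scaled loading maps; plus PCA shape features of the
  cross-section profiles.

Because the raw recordings of such studies are rarely deposited,
`otokin.synthetic_data` generates all three input modalities with analytic
ground truth — landmark trajectories (burst-and-glide or continuous
presets), stimulus-locked eye traces, paired eye–tail traces, and voxelized
elliptic-torus canal phantoms with ampulla bulge and optional pre-ampullary
stenosis. Species presets (`xenopus_54`, `axolotl_54`) bundle published
stage-54 group means so every estimator can be exercised against known
targets.

## Worked example

Simulate a continuous-swimmer recording at the published stage-54 means and
run the bout analysis:

```bash
$ otokin simulate swim --preset xenopus_54 --seed 1 --out sim
wrote sim/landmarks.csv (1800 frames)
$ otokin analyze swim --landmarks sim/landmarks.csv --fps 30 --pixel-scale 0.1 --out ana
4 bouts, 28.53 s swimming (47.6%)
```

The preset scripts bouts totalling 28.8 s of the 60 s recording (the
published *Xenopus* mean); dual-threshold detection recovers 28.53 s —
within a frame or two per bout edge. The same round trip for the
optokinetic reflex of an axolotl:

```bash
$ otokin simulate eyes --preset axolotl_54 --condition okr --seed 1 --out eyesim
$ otokin analyze eyes --trace eyesim/trace.csv --out eyeana
OKR: gain 0.250, phase +6.0 deg
```

i.e. the full preprocess → segment → average → gain/phase chain returns the
generator's programmed gain (0.25, the published axolotl OKR mean) and its
slight phase lag (+6.03°) to estimator precision. In the library the same
chain is three calls:

```python
from otokin.synthetic_data import eye_preset, simulate_eyes
from otokin.oculomotor import estimate_gain_phase

res = simulate_eyes(eye_preset("xenopus_54", "vor_dark"))
gp = estimate_gain_phase(res.trace)   # gain 0.290, phase -54.3 deg (lead)
```

Canal phantoms close the loop on morphometry: a half-torus at the published
axolotl radii (R = 582.91 μm, r = 66.32 μm, 2 μm voxels) yields a
cross-section profile whose mean-equivalent lumen radius comes back within
0.3%, and the X_max model then ranks the axolotl canal below the *Xenopus*
one (R = 634.09 μm, r = 77.11 μm) in relative sensitivity.

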