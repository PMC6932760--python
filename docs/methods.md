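# Methods

## The measurement model

The pipeline quantifies relocalization of fluorescent ER markers to mitotic
spindle poles in time-lapse movies of syncytial-embryo fields. Its unit of
measurement is a fixed circular ROI of 2 µm diameter (configurable), placed
either at a spindle pole or in free cytoplasm. For each ROI on each frame
the package extracts the arithmetic mean and the maximum of the pixels whose
centres lie strictly inside the disk (half-open inclusion: distance <
radius, which makes rasterized areas deterministic when a pixel centre falls
exactly on the circle), plus the unweighted centroid of those pixel centres
in micrometres. Coordinates are physical, with the origin at the centre of
pixel (0, 0).

ROIs are linked across frames by greedy nearest-neighbour matching on
centroid distance: candidate links are consumed in ascending-distance order,
each ROI matches at most once per frame transition, links longer than the
gate (default 2 µm, one ROI diameter) are forbidden, and ties break toward
the lower ROI id. Spindle and cytoplasm ROIs are linked independently, and
there is no gap closing — a track missing any frame of the window is
excluded from fold-change statistics and reported separately. Greedy
matching equals the minimum-total-distance assignment whenever nearest
neighbours are mutual, which holds by a wide margin here: pre-NEB pole
movement is sub-pixel-to-sub-micron while poles of different nuclei are
several micrometres apart. The test suite probes both the mutual and the
non-mutual branch explicitly.

Each complete track is normalized to its own first frame:
F(t) = I(t)/I(0), so F(0) = 1 exactly and enrichment is F(t) − 1. Because
spindles only become morphologically visible a few frames into mitosis,
pole ROIs for the earliest frames are "backfilled": identical-centre copies
of the first-visible-frame ROIs. This is justified by the pre-NEB motion
bound the package itself measures (standard error of the mean between-frame
step well under 0.3 µm, small against a 2 µm ROI).

## Statistical layer

* **Welch's t-test** (implemented from the statistic and the
  Welch–Satterthwaite degrees of freedom, with the t CDF from scipy):
  two-sided everywhere; sidedness is not configurable because every
  reported comparison is two-sided. Identical groups give t = 0, p = 1; a
  comparison of two zero-variance groups is undefined and raises. No
  multiple-testing correction is applied by default (per-timepoint p-values
  are reported raw); a Benjamini–Hochberg adjustment is available.
* **Two-phase kinetics**: independent OLS lines on [0, t_b] and
  (t_b, t_end], with the boundary point assigned to phase 1. The default
  breakpoint is 540 s — the prophase/prometaphase boundary (NEB) in the
  long-movie presets. Each phase needs at least two points.
* **Displacement**: d(t) = ‖p(t) − p(0)‖ per track; the linear model is
  d ~ t (OLS slope, R², two-sided p). A flat (all-equal) series is reported
  as slope 0, R² = 0, p = 1 rather than NaN. The step statistic is
  SE = sd(step sizes)/√(n steps). d is invariant to global translation and
  rotation of the trajectory.
* **Rocking**: the signed angle between the pole-pair vector
  p_b(t) − p_a(t) and its T0 direction, computed with atan2 (wrapped to
  (−180°, 180°]); the amplitude is the maximum absolute tilt.

In compiled group summaries, the "baseline" Welch comparison uses the
frame-1 fold distribution, because frame-0 folds are exactly 1 for every
track by construction (zero variance); the degenerate identical-constant vs
identical-constant case that still arises in control-vs-control comparisons
at frame 0 is mapped to t = 0, p = 1 so tables remain total.

## The synthetic-movie generator

The generator emulates a cortical field of synchronously dividing nuclei:

* **Scene**: a uniform cytoplasmic background b·g(t) (b = 1000 counts by
  default) with nuclei as dimmer disks (radius 2.5 µm) and one isotropic 2-D
  Gaussian spot per pole (σ = 0.75 µm by default) at ±3.5 µm from the
  nucleus centre along a per-nucleus random axis. Movies are 16-bit,
  0.1 µm/px, 512×512 by default; nuclei sit on an even grid with an edge
  margin large enough for all pole excursions, and a second channel renders
  the nuclei.
* **Kinetics**: the cytoplasm declines linearly by `cytoplasm_depletion_frac`
  (default 10%) over the movie. The relative pole-ROI intensity r(t) is
  piecewise linear with slopes s₁ (before `phase_break_s`) and s₂ (after),
  capped so the pole fold change r(t)/r(0) never exceeds
  1 + `peak_enrichment`. At every frame the spot amplitude is calibrated
  against the rasterized pole-centred measurement disk so that the disk's
  mean intensity equals b·r(t) exactly — the measured series *is* the
  programmed series in the noise-free, pole-centred case, which is what
  makes end-to-end parameter recovery a sharp test. The maximum intensity
  then follows mechanically from the spot shape: its enrichment is the mean
  enrichment divided by the disk-averaged Gaussian, so the max/mean ratio
  is set by σ. The ReepB-like preset uses σ = 0.664 µm, the width at which a
  +0.2 mean-fold peak reads +0.4 in max intensity under 10% depletion.
* **Motion**: the pole-pair axis rocks about the nucleus centre by
  A·sin(2πt/T) (default T = 140 s, so 35 s frames sample the extremes
  exactly). Before NEB each pole jitters independently (per-axis Gaussian,
  frame 0 excluded — time 0 is the displacement reference). After NEB the
  pair translates along its axis on a linear ramp whose endpoint is solved
  (a small quadratic accounting for the rocking contribution on the adverse
  pole) so that the maximum displacement from T0 equals exactly
  `post_neb_drift_max_um` at the final frame and never exceeds it earlier.
* **Noise**: additive Gaussian after scene composition (default sd 5 counts
  on a background of 1000, matching high-SNR confocal/HCA acquisitions),
  then rounding to uint16.

### Presets

Presets bundle the study conditions the package is validated against; each
encodes the headline values its name refers to:

| preset | encodes |
|---|---|
| `fig1d_rtnl1` | +0.2 peak mean-fold spindle enrichment, 10 frames × 35 s, 20 nuclei |
| `fig1f_reepb` | +0.4 peak max-fold / +0.2 mean-fold (σ = 0.664 µm) |
| `fig2_rtnl1` | two-phase trace, s₁ = 0.01024/s, s₂ = 0.06733/s, break 540 s, 23 frames × 30 s |
| `fig2_kdel` | s₁ = −0.004510/s, s₂ = 0.1116/s, pole baseline 3× background |
| `fig1b_displacement` | ±5° rocking, 0.15 µm pre-NEB jitter sd, 0.9 µm max post-NEB displacement |

Two preset-design notes. First, the KDEL-like two-phase trace declines
before NEB; a T0-normalized nonnegative series cannot sustain a slope of
−0.00451/s over 540 s, so the two-phase traces are interpreted (and fit) in
*baseline-normalized intensity units* — the raw ROI mean divided by the
known background gain — with the KDEL pole baseline set to 3× background.
For the Rtnl1-like preset (baseline 1×) this coincides with T0 fold change.
Second, the enrichment presets set the rocking amplitude to zero: a 5°
rock displaces a pole ~0.35 µm tangentially, which would systematically
depress the enrichment measured by a static ROI; the motion values live in
`fig1b_displacement`, the enrichment values in the fig1/fig2 presets.

### What the generator does and does not emulate

It reproduces the *measurement situation*: fold-change kinetics seen through
fixed rasterized ROIs, pole motion at the scale that matters for ROI
placement and tracking, and realistic intensity scales and noise. It omits
optics (no PSF; spots are rendered Gaussians), Poisson shot noise,
photobleaching, nucleus movement, intensity heterogeneity between nuclei,
and 3-D structure (Z-stacks are supported in I/O via max projection but the
renderer is 2-D). Recovery tests therefore demonstrate that the pipeline
measures what it claims on images with known truth — they do not validate
segmentation-free operation on real embryo movies, where ROI placement
remains the analyst's responsibility (via the placement-file interface).

## Numerical choices and degenerate inputs

* Rasterized-disk centroids deviate from the true centre by ~0.01 µm
  (quantization), which propagates to ~0.05–0.15° in recovered rocking
  amplitudes and ~0.01–0.02 µm in maximum displacements at the default
  geometry; both are inside the reported tolerances.
* ROI overlaps resolve to the lowest id (and an ROI left with zero pixels is
  an error, as is one fully outside the image).
* Movie I/O refuses values outside [0, 65535] or non-integral floats rather
  than clipping; masks are stored as 16-bit PNG (lossless) rather than a
  lossy format, preserving the save-once/re-extract-later workflow.
* Backfilled ROI copies keep their id when it is free on the target frame
  and are renumbered otherwise (ids only need per-frame uniqueness; tracking
  identifies ROIs by centroid).
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical parameters give bit-identical
  movies and ground truth.

## Problem sizes

The validation suite and the reproduction script use the presets at their
native sizes: 512×512 px × 10 frames × 20 nuclei for enrichment/motion
recovery (20 seeds for stochastic quantities) and 256×256 px × 23 frames
for the single-pole two-phase traces. A full reproduction run completes in
about a minute on one CPU.
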