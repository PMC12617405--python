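# Methods

This note records the models, estimator rules, parameter choices and known
limitations behind each analysis stage, in the spirit of a methods section:
everything here is implemented and exercised by the test suite; no number
is claimed that the code does not compute.

## Movies and calibration

A movie is a T×H×W grayscale stack with user-supplied calibration (μm/px,
s/frame). Calibration is deliberately *not* read from TIFF tags — tag
dialects vary across acquisition software, and silent unit errors are worse
than an explicit argument. All coordinates are 0-based (row, col) pixels;
frame indices are 0-based. Typical acquisition regimes for gliding assays
are 100 ms intervals over 20 s (fast cardiac myosin) or 1 s over 60 s
(non-muscle myosin II); the defaults throughout describe the latter.

## Filament segmentation

Frames are lightly smoothed (Gaussian, σ = 1 px) and thresholded. Two
deterministic methods are provided: Otsu (default) and k·σ — a threshold k
robust-background SDs above the robust background level, where the robust
level/noise are the median and 1.4826·MAD of the smoothed frame, estimators
insensitive to the minority of filament pixels. The Otsu threshold is
floored at median + 3·robust SD so that filament-free noise frames yield
zero objects instead of Otsu's arbitrary split of a unimodal histogram.
Connected components below `min_area_px` (default 6) are dropped.

An interactively trained pixel classifier could substitute here; the
deterministic rules were chosen so that identical inputs always give
identical outputs with no trained model to version. The downstream event
threshold needs only a filament/background partition, which either method
provides. The k·σ method is offset-invariant by construction.

Filament length is the geodesic length of the skeleton of the object mask
(1 per orthogonal step, √2 per diagonal) times the pixel size; this
underestimates the true contour length by roughly one PSF width of end
erosion, which stays within 10 % for filaments ≳ 2 μm at 0.108 μm/px.
Background statistics are pooled over the label-0 pixels of *all* frames,
one (mean, SD) pair per movie.

## Tracking and motility metrics

Linking is greedy globally nearest-pair between open track heads and the
next frame's centroids, accepting pairs within `max_disp_um` (default
2 μm/frame, scaled by the gap length when bridging up to `max_gap` = 2
missed frames); ties break deterministically toward lower track id and
label. At gliding-assay densities (well-separated filaments moving ≲ 1
μm/frame) this matches globally optimal assignment while remaining
order-independent and auditable.

Speed is the mean over consecutive track points of displacement divided by
actual elapsed time. "Moving" requires both mean speed > 0.05 μm/s and net
displacement > 0.5 μm — the dual criterion excludes stationary filaments
whose centroids jitter with noise (apparent jitter speeds are ~0.02–0.03
μm/s at the default simulation noise). Note that wobble displacements
(1 μm jumps) can legitimately push an otherwise stationary filament over
the net-displacement bar; percent-moving is therefore interpreted together
with the event frequency. Because "filaments per movie" is ambiguous
between objects and trajectories, summaries report both the mean per-frame
segmented count and the track count.

## Detachment/wobbling detection

The detector is the pipeline's core: blur each frame (Gaussian, σ =
`blur_radius_px` = 2 — "blur radius" is read as σ, the common
imaging-software convention), divide consecutive blurred frames
(ratio frame i = frame i+1 / frame i, with an epsilon guard of 10⁻⁶ times
the movie median added to both numerator and denominator), and threshold at
1 + k·(SD/mean) of the movie background with k = 4. Supra-threshold
components of at least `min_spot_area_px` = 4 pixels become candidate
spots; spots of the same polarity within 5 px in consecutive ratio frames
merge into one event (a single physical event can exceed threshold in two
successive ratios). The threshold formula is scale-invariant: multiplying
the movie by any constant changes neither the ratios nor the cutoff.

Detection is one-sided (brightening only) by default, matching the 1.3–3
display scale of the ratio projection. A filament that vanishes without
reappearing only *darkens* its old position, so the `two_sided` option
additionally thresholds the inverted ratio; benchmarks that include
detachments use it. Wobbling and detachment are not distinguished in
output (`kind = unclassified`): a wobble produces a brightening spot at the
new position and a darkening one at the old, a detachment only the latter,
and no rule on a single ratio frame separates them reliably.

In the temporal max projection, the brightening projection marks new
positions; vacated positions appear in the projection of the inverted
ratio (the one-sided projection cannot show them, since a darkened pixel's
ratio is below 1 in exactly one frame and ≈ 1 elsewhere). The PNG rendering
clips to [1.3, 3] and uses matplotlib's `inferno`, a perceptually uniform
stand-in for the classic "FIRE" lookup table.

Events are attributed to the track whose centroid at either flanking frame
is nearest (within `max_disp_um`); the movie-level frequency is assigned
events per track, with unassigned events reported separately.

## Synthetic gliding movies

The generator emulates what the detector and tracker must cope with, not
filament physics. Contours are smooth random curves (tangent-angle random
walk, 0.05 rad/√px) sampled every 0.25 px of arc; a motile filament slides
along its own precomputed path, which is how gliding filaments actually
move. Wobbles laterally displace the whole filament by `wobble_jump_um`
(1 μm) within one frame, persistently; detached filaments vanish for all
later frames (re-landing elsewhere would just be a new filament to the
pipeline). Event times are Poisson with the configured per-filament rates
while attached; placement keeps each filament's full swept path, including
its largest cumulative wobble excursion, inside the field, and an optional
minimum-separation constraint gives non-overlapping scenes for identity
tests. Rendering stamps the contour with uniform line mass, convolves with
a Gaussian PSF (σ = 1.5 px), and adds constant background plus Gaussian
noise; the stamped mass is normalized so the PSF-convolved ridge peak
equals `filament_amplitude`.

Defaults: 10 filaments of 3 ± 1 μm, 0.1 μm/s gliding (a realistic
non-muscle myosin II speed; it also keeps a 60 s trajectory inside a
128-px field at 0.108 μm/px), motile fraction 0.6, wobble 0.02/s, detach
0.01/s, background 100 ± 6, amplitude 60. The amplitude-to-noise ratio of
10 is a deliberate choice: the k = 4 threshold demands a blurred relative
change above 4·SD/mean, and the σ = 2 detection blur attenuates a thin
filament's contrast by a factor σ_t/√(σ_t² + 4) ≈ 0.6, so event recall
only becomes attainable above amplitude ≈ 7·SD. At the default settings
the detector operates with a ~1.5× contrast margin — non-trivial (recall
is ~0.97, not 1.0) but stable. Gaussian (not Poisson) noise is used
because the threshold formula consumes only a background mean and SD.

Not emulated: photobleaching, fixed-pattern noise, filament crossing
resolution, out-of-focus light, re-binding of detached filaments. Passing
benchmarks therefore demonstrate correctness of the *analysis* under the
stated noise model, not performance on any particular microscope's data.

The standard event benchmark (used in the acceptance tests) runs 15
stationary filaments per movie at wobble 0.033/s and detach 0.012/s for
60 s — ≈ 30 ground-truth events per movie — with two-sided detection.
Stationary, because a gliding filament's advancing tip also brightens
frame-to-frame without being a discrete event; frequently
wobbling/detaching, poorly translocating filaments are precisely the
phenotype the detector targets. A detection matches a true event when
their frame windows agree within one ratio frame and the spot centroid
lies within 5 px of the affected filament's contour just before or after
the event (spots are filament-shaped and may fragment, so
centroid-to-centroid distance is the wrong metric).

## Cell morphometry

Volume and surface area follow the spherocylinder closed forms (length
includes the hemispherical caps; length ≥ width > 0 is enforced, and at
L = w both reduce exactly to the sphere). Cohort summaries compute per-cell
values first and then average — the formulas are nonlinear, so this
differs from evaluating at the mean dimensions, by under 1 % at the ~7 %
coefficients of variation typical of these cohorts (the Jensen-gap bound
is tested by simulation at CV ≤ 10 %). Records violating length ≥ width
are dropped per cell with a logged warning rather than failing the cohort.
Between-strain comparisons use the rank-sum test in its tie-corrected
normal approximation; exact enumeration is infeasible at n > 50 and the
effect sizes of interest put p-values far from any decision boundary.
Cohort presets: MEEE (wild-type N terminus) 13.54 ± 0.98 × 4.10 ± 0.27 μm;
REE (arginylated actin) 11.76 ± 0.90 × 4.24 ± 0.31 μm.

## Cytokinesis phase timing

A ring trace samples (time, state ∈ {nodes, ring, done}, diameter) on a
regular grid, typically 3 min. Phases are segmented by reproducible
changepoint rules rather than by eye:

- **coalescence** — first `nodes` sample to first `ring` sample;
- **initial diameter** — median of the first `smoothing_window` (3) ring
  diameters;
- **constriction onset** — the sample *preceding* the first whose
  median-smoothed diameter drops more than `dwell_tolerance_frac` (5 %)
  below the initial diameter. The preceding-sample convention matters: the
  diameter at the onset frame itself is still the initial one, and taking
  the first sub-threshold sample instead would bias every dwell estimate
  up and every constriction estimate down by one frame;
- **end of constriction** — the first `done` sample when the trace has
  one; otherwise the first ring sample below `end_diameter_um` (0.5 μm),
  a fallback for real traces where the ring spot never cleanly vanishes.
  Traces that do neither raise a censoring error and are excluded from
  summaries.

Durations snap to the sampling grid (no subframe interpolation — the data
are 3-min sampled and manual timings of such movies are grid multiples
too). Two identities are enforced on every output, not approximated:
total = coalescence + dwell + constriction exactly, and rate ×
constriction = initial diameter to 10⁻⁹ relative error. The constriction
rate uses the *initial* ring diameter ("ring diameter divided by the time
for constriction"); a mean-cell-width proxy would be a caller-side
substitution of the diameter argument.

The 5 % onset rule is a documented default, not a claim about how any
published dataset was timed by hand; with 3-min sampling it detects onset
one frame late only for rings constricting slower than ~60 min
end-to-end, a small bias the parameter-recovery tests bound.

The trace generator draws the three phase durations per cell from normal
distributions truncated at one frame and rounded to the nearest grid
multiple (state transitions are only observable on the imaging grid), and
the initial diameter from 3.7 ± 0.2 μm — chosen because published
rate × constriction-time products for both strains cluster at 3.6–3.8 μm,
i.e. the ring diameter at constriction onset roughly equals the cell
width. Phase-statistic presets (minutes): REE coalescence 20.52 ± 2.69,
dwell 5.64 ± 2.64, constriction 45.48 ± 12.27; MEEE 16.20 ± 2.12,
8.88 ± 2.52, 34.32 ± 6.66; 25 cells per cohort at 3-min sampling.

## Numerical and interface choices

- Blur boundary handling is reflective; the blur is validated against a
  dense separable-kernel convolution oracle to 10⁻⁶.
- CSV floats are written with ≥ 6 significant digits; identical inputs and
  seed give byte-identical outputs.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  simulation is bit-reproducible from its config.
- Problem sizes in the test suite (128–256 px fields, 20–60 frames, 20-seed
  replicates, 100-cohort replicates for phase recovery) are chosen as the
  smallest at which the binomial/CLT bounds being asserted are still
  meaningfully tight.

## Known limitations

Crossing or overlapping filaments are segmented as one object (tracking
identity degrades gracefully but is not guaranteed through contact);
events are not subclassified into wobble vs detachment; no drift
correction; no subpixel localization; morphometry assumes manually
measured dimensions rather than segmenting cells from images; ring
diameters are taken as given rather than extracted from fluorescence.
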