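# Methods

## The measurement

A depth camera mounted 250 cm above a flat board looks straight down at a
single standing hen.  Every depth pixel reports the distance from the
camera to the first surface below it, so the height of that surface above
the board is

    height = floor_distance − depth.

Pixels with depth below a threshold of `floor_distance − clearance`
(clearance 5 cm by default, i.e. a 245 cm cutoff for a 250 cm camera)
form the foreground mask; everything at or beyond the threshold is board.
The maximum height in a frame is `floor_distance − min(masked depth)`, the
minimising pixel is the "peak pixel" marked on verification overlays, and
a wing-flapping bout reduces to the maximum over its frames.  The depth
stream runs at 90 fps (640×480); a 30 fps colour stream (1280×720) is
cropped and rescaled onto depth coordinates purely for visual checks —
every depth frame is analysed, not just the paired ones, because pairing
by nearest timestamp exists only to attach a colour frame to a
measurement, and averaging or subsetting depth frames would bias the
minima the measurement depends on.

Thresholding is strict (`depth < threshold`) so that under exact
arithmetic the floor can never enter the mask.  Heights are computed
against the *calibrated* floor distance by default; both the nominal and
calibrated values are recorded in the report, along with which one was
used.

### Geometric caveat

The subtraction treats every pixel as if it looked straight down
(orthographic geometry).  A real camera sees off-axis points along
slanted rays, so heights measured far from the image centre are slightly
distorted.  The pipeline implements the literal subtraction; the
synthetic renderer uses the same orthographic model, so validation
against it cannot detect this distortion.  Treat off-centre heights from
real wide-angle footage with appropriate caution.

## Floor calibration

The floor distance is estimated from empty-scene frames as the median
across frames of the per-frame median depth over the central 50% of rows
and columns (edges of the board and pen-wall artefacts are excluded);
dispersion is the median absolute deviation of the per-frame medians.  A
plane fit is deliberately not attempted: the protocol treats the board as
one flat reference at a single distance, and a tilt model is left as an
extension.  The median makes the estimate exact on constant frames and
insensitive to dropout up to half the pixels.  Rig verification measures
an object of known height via the same min-depth path and reports the
signed error; the accept/reject tolerance is left to the deployment.

## Speckle handling

Two modes exist and the active one is always recorded:

* **faithful** (default): raw minimum, no filtering, components of any
  size.  This mirrors a protocol that reports the raw minimum distance.
* **robust** (`--robust`): a 3×3 median prefilter must also clear the
  threshold for a pixel to enter the mask, and 8-connected components
  smaller than `min_component_px` (5) are dropped.  This suppresses
  isolated hot pixels, which otherwise set the height single-handedly.

The robust mode gates the *mask* only; the height is still read from the
raw depth of the surviving pixels, so a genuinely elevated surface is
never eroded by the filter.

### Noise and the extreme-value bias of a max-of-min estimator

The bout maximum is the extreme over every masked pixel of every frame.
With independent per-pixel Gaussian depth noise of SD σ, the measured
maximum sits above the true one by roughly the expected extreme of the
N noise draws taken near the true peak — about 3σ once N reaches a few
hundred, i.e. ~0.9 cm at σ = 0.3 cm.  The validation suite measures this
directly: over 20 synthetic bouts at default noise the mean absolute
recovery error is ≈ 0.97 cm and the worst bout ≈ 1.1 cm, dominated by
this positive bias rather than by quantisation (≤ 0.05 cm) or rendering
error (the renderer places the analytic wing-tip height exactly).  This
is an inherent property of a max-of-min estimator under iid noise, not an
implementation defect; no single-frame filter fixes it, because gating
the mask leaves raw extremes in place while median-filtering the values
erodes the thin wing tip (the height gradient across the tip is
`tan(elevation) × pixel pitch` ≈ 1.9 cm per pixel near the peak).  Users
comparing absolute heights across sensors with different noise floors
should expect a bias of roughly the noise extreme, upward.

## Synthetic scenes

The generator emulates the recording geometry, not a photorealistic hen:

* **Rig** — camera 250 cm above the board, depth 90 fps at 640×480,
  colour 30 fps at 1280×720, board 121 cm square.  Pixel pitch defaults
  to 0.6 cm on the floor plane, representative of a consumer stereo-depth
  sensor's footprint at 2.5 m.
* **Bird** — a half-ellipsoid body (35×16 cm footprint, 34 cm apex) with
  two planar wing panels hinged at 30 cm shoulder height.  Wing elevation
  follows a rectified sinusoid between the rest angle (10°) and the peak
  angle (72°) at 4 Hz for 2 s, so wings never dip below rest — a
  stationary flap throws the wings upward.  None of these dimensions are
  published measurements; they are plausible placeholders for a mature
  white egg-laying strain, chosen once.  The analytic peak,
  `shoulder_height + wing_length·sin(peak_angle)`, lands near 50 cm —
  the scale such birds reach.
* **Sensor** — additive iid Gaussian depth noise (σ 0.3 cm) on valid
  pixels, 2% dropout to the invalid code (0), and quantisation to the
  0.1 cm storage unit.
* **Rendering** — orthographic z-buffering of the surface heightfield;
  the wing panels are scatter-sampled at a third of a pixel so the exact
  tip height always lands in its pixel (closed-form agreement within
  0.05 cm noiseless).  The colour render is the depth field of view
  uniformly rescaled and centred on the wider RGB canvas, which makes the
  RGB→depth registration map known exactly.

What the renders do **not** contain: perspective rays, plumage texture,
motion blur, wing flexibility, multi-path or edge noise correlated with
geometry, walls of the test pen, or any behaviour beyond the single
stationary flap.  Passing the recovery tests therefore demonstrates the
measurement chain's arithmetic and its response to iid noise — it does
not certify performance on real stereo-depth artefacts.

## Cohorts and statistics

Synthetic cohorts draw (weight, folded wing, extended-to-primary,
extended-to-phalange) from a Gaussian copula with configurable pairwise
correlation (identity by default: the deposited cohort's table was
null-like).  Marginals: weight 1.56 ± 0.10 kg; folded wing 19.0 ± 1.2 cm;
extended-to-primary 29.0 ± 1.8 cm; extended-to-phalange 21.0 ± 1.4 cm —
plausible for the strain, chosen once.  Per-hen kinematics tie the wing
panel length to the skeletal extended-wing measure while shoulder height
(30 ± 3 cm) and peak elevation (72 ± 8°) vary independently, so flap
height couples only weakly to any single body measure, emulating the
reported absence of correlations.  Records violating positivity or the
feathers-past-bone constraint are flagged, never dropped silently.

The statistics stage:

* **Summaries** — n, mean, SD (n−1), median, quartiles by linear
  interpolation of order statistics (type-7; box-plot panels depend on
  the convention, so it is fixed and documented).
* **Outliers** — Tukey fences at k = 1.5 per variable; flagged values are
  excluded pairwise-complete from correlations and the exclusion logged.
  At very small n (≲ 10) the fences are aggressive; they are intended for
  cohort-sized samples (n ≈ 28).
* **Normality** — Shapiro–Wilk (scipy), suited to small samples.
* **Correlation** — tie-corrected Spearman: mid-ranks, product-moment
  correlation, two-sided p from the t approximation on n−2 df, exact
  enumeration of all n! permutations when n ≤ 8.  A constant input
  reports an undefined correlation rather than a number.  The 10-pair
  table (weight, three wing measures, flap height) is emitted in a fixed
  order with no multiple-comparison correction, matching the analysis
  convention it reproduces.

## Containers

Sequences are stored as a directory of 16-bit grayscale PNGs (unsigned
millimetres, 0 = no return, so quantisation error is ≤ 0.05 cm by
construction) plus 8-bit RGB PNGs and a JSON manifest holding rig
metadata, integer-microsecond timestamps, provenance, and optional ground
truth.  Reading validates monotone timestamps and refuses manifests whose
frames are missing, naming the first absent file.  The morphometrics
table is a CSV with canonical headers (an XLSX reader that merges
worksheets on hen id, with a column-mapping option, covers
spreadsheet-shaped sources whose exact layout is unknown in advance).

## Problem sizes in the validation suite

Module tests run on reduced rigs (120×160 or 40×60 pixels) that exercise
identical code paths; full-resolution 640×480 sequences are used where
the claim depends on pixel count (noise-SD calibration, floor-estimate
concentration, the 20-bout recovery study, and the acceptance script's
28-hen cohort).  The recovery and cohort studies use 2 s bouts; the
known-object check uses a small block so the min-depth extreme stays in
its 3σ envelope (see the extreme-value note above).
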