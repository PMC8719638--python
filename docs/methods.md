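# Methods

`polarpunc` quantifies the behaviour of diffraction-limited protein puncta
(a WASP-family nucleation-promoting factor is the motivating marker) on the
ventral surface of fast-migrating amoeboid cells, together with the
surrounding measurements: curvature-driven enrichment at substrate-attached
beads, Pearson colocalization with a rotation null, and whole-cell
migration statistics. Every analysis stage is validated against a
synthetic-scene generator whose event statistics are calibrated to the
population numbers the analyses are expected to recover.

## Cell-frame coordinates

A migrating cell defines a polarity axis from its rear to its front. A
point's position along that axis is its scalar projection as a fraction of
cell length: `p` (rear = 0, front = 1) or, equivalently, `q = 1 − p`, the
distance from the front. Both conventions are exposed; all headline
statistics are quoted in `q` ("percent of cell length from the front").
Projections outside `[0, 1]` are clamped and flagged rather than dropped.

Anchors (front, rear, top, bottom) are located automatically: the
boxcar-smoothed centroid velocity orients the axis, and the mask contour's
extremal projections give the anchor points, averaging the flat pixel
plateau at each tip. Cells whose speed falls below 0.05 px/frame cannot be
oriented and raise an error unless a manual-anchor table is supplied; a
manual table always overrides automation frame by frame.

## Synthetic scenes

The generator renders a polarized elliptical cell (length 15 µm, width
9 µm) translocating at 10 µm/min, imaged at 0.16 µm/px every second —
values representative of under-agarose neutrophil-like cell imaging. The
heading follows `θ' = θ − b·sin(2θ)·Δt + N(0, σ_θ)`: `b = 0` is an
unbiased persistent random walk, `b > 0` mean-reverts the heading to the
x axis (nanoridge contact guidance; both `θ = 0` and `θ = π` are stable, as
alignment is an axis, not a direction). Masks are exact ellipses; the
irregular contours of real cells are deliberately out of scope, and
segmentation robustness is tested with rendered, noisy frames instead.

### Punctum event model

Puncta nucleate as a Poisson process (default λ = 0.5 events/frame), are
fixed to the substrate (unless retrograde flow is enabled), and are removed
once the advancing cell carries their relative position past a per-event
death threshold. Each event draws a `(q_b, q_d)` pair from independent
normals, accepted only when `0 ≤ q_b, q_d ≤ 1` and `q_d ≥ q_b + δ`. The gap
δ guarantees a minimum lifetime of `δ·L/(v·Δt)` frames so that every event
is trackable by a 2-frame minimum-duration filter; δ = 0.03 (≈2.7 frames at
defaults).

The raw parameters are **calibrated** so the *accepted-pair* statistics hit
the three population targets: mean appearance 0.198, mean extinction 0.374,
and P(extinction ≤ 0.5) = 0.84. The truncation `q_d ≥ q_b + δ` reshapes the
death distribution substantially, so the raw parameters
(µ_b = 0.2122, µ_d = −0.1515, σ_d = 0.3047, at σ_b = 0.05) look nothing
like the targets; only realized statistics are meaningful. Calibration
expresses the realized statistics as smooth 1-D quadratures (conditioning
on `q_b`; truncated-normal moments are closed-form, with survival functions
for tail accuracy), solves them with bounded least squares, and verifies the
solution against a fixed-seed Monte-Carlo resampling to ±0.002. The
calibrated constants ship as package defaults and a test re-derives them.
At δ ≥ ~0.04 the three targets become jointly unattainable for this family
(the accepted-birth floor forces the death mean up once 16% of mass must
sit beyond mid-cell); calibration then raises an explicit error.

Newborn puncta resample their *lateral* slot (never the axial position, so
the calibrated statistics are untouched) until they are at least 4 PSF
sigmas from every live punctum: closer twins are unresolvable by any
diffraction-limited detector and would silently cap achievable recall.

### Rendering

Channels: main marker, a rear-biased second marker (mean q = 0.71, never
placed within 4 PSF σ of a main-marker punctum; a colocated mode re-uses
the main-marker positions for control experiments), bead fiducials, and a
cytoplasm channel (softened ellipse). Spots are 2-D Gaussians of the PSF
width (σ = 1.3 px). Noise is Poisson shot noise on gain-scaled intensities
plus Gaussian read noise; a smooth multiplicative flatfield is optional.
The camera model is a package choice — acquisition noise statistics are
not part of the study conditions. `SceneConfig.amplitude_for_snr` converts
a desired peak signal-to-noise ratio (peak amplitude over background noise
σ) into a punctum amplitude; validation scenes use SNR 8 unless a test is
explicitly about SNR dependence.

## Punctum detection

Per frame: optional flatfield division (field normalized to mean 1) → DoG
band-pass (σ = 1.3/2.6 px) → weighted Otsu threshold over the positive DoG
response (weight 1.0; the weight is the knob the original workflow tuned
manually) → local maxima at ≥3 px separation → 2-D elliptical Gaussian fit
(Levenberg–Marquardt with analytic Jacobian) in a 9-px window. A punctum's
integrated, background-independent signal is the volume under its fitted
Gaussian, `2π·A·σx·σy`.

Two automated gates replace the original workflow's manual confirmation of
each maximum:

* **cell-edge exclusion** — maxima within 4 px (Euclidean distance
  transform) of the cell boundary are discarded; the membrane edge produces
  a band-pass ridge about `2σ_large` wide that a human would reject on
  sight;
* **amplitude gate** — fitted amplitude ≥ 4× a robust noise estimate. The
  noise is 1.4826 × MAD of the DoG background, divided by the DoG filter's
  white-noise gain so it is expressed in image units and can gate the
  fitted amplitude dimensionally consistently.

DoG sigmas, the Otsu weight and both gates are documented choices, not
reproductions of unpublished settings. A review CSV can override keep/drop
per detection.

## Tracking

Per consecutive frame pair, linking solves the globally minimal-cost
one-to-one assignment with squared Euclidean cost, links forbidden beyond
`max_displacement`, and `max_displacement²` charged per unlinked endpoint
(the augmented linear-assignment construction). An exhaustive-enumeration
oracle checks optimality on every small instance. Gap closing joins track
ends to later starts within `max_gap` skipped frames at radius
`max_displacement·(gap+1)`.

`max_displacement` defaults to 1.5 px/frame: substrate-fixed puncta move
only by localization jitter (~0.3 px), and the gap-closing radius must stay
below the typical punctum spacing or gap closing chains distinct events
into one track (this inflates lifetimes and deletes appearance/extinction
samples in a correlated way). EDTA-mode analyses raise it explicitly.
Tracks shorter than 2 frames are dropped; interior-events mode further
drops tracks touching the first or last movie frame, whose true birth or
death is unobserved.

A track is substrate-fixed when its mean per-frame lab displacement is
below ε = 0.5 px/frame, otherwise flowing (with its mean speed and
direction reported). At the localization jitter above, stationary tracks
measure ~0.26 px/frame, leaving a comfortable margin to ε on both sides.

## Event-position statistics and two estimator corrections

Appearance and extinction positions are the first/last detections of each
kept track mapped through the cell outline of their own frames. Two biases
of the naive recipe matter at the population level and are corrected in the
acceptance pipeline (both off by default in the library API):

* **censoring window** — dropping tracks that persist past the movie end is
  *length-biased*: it removes exactly the long-lived, far-travelling
  events, inflating the extinguished-by-midline fraction by ≈ +2.5
  percentage points on 300-frame movies. Restricting to births early
  enough that any event's death is observable (lifetime is bounded by
  `L/(v·Δt)` frames because `q_d ≤ 1`) removes the bias exactly.
* **sub-frame extinction** — a punctum disappears somewhere between its
  last visible frame and the next, so the last-frame position under-reads
  the extinction threshold by half a frame's relative advance (0.56% of
  cell length at defaults). `event_positions(...,
  subframe_disappearance=True)` extrapolates half a frame at the track's
  final drift rate, the median-unbiased estimate of the crossing point.

Appearance needs no such correction: events exist at their birth frame at
exactly the drawn position.

## Bead enrichment

Bead positions are detected once on a reference frame (or loaded) and
treated as stationary. Marker signal at a bead is quantified as the fitted
Gaussian volume (background-independent); an unfittable bead propagates a
NaN marker that `fraction_positive` counts as negative rather than
discarding. Volumes are normalized per membrane area using the full sphere
surface `π·d²`; whether the wrapped cap or the full sphere is "the" area is
unknowable from the source, and the full sphere is the only parameter-free
choice — all size *ratios* are unaffected.

Position-resolved traces sum a 9-px box around the bead; a local-median
ring (restricted to cell-interior pixels) estimates the cytoplasmic
background under the box. Traces only include frames where box and ring
are completely under the cell (margin = box half + 5 px): edge-crossing
frames corrupt the background estimate in a position-correlated way.
Profiles normalize each bead to its own maximum, discretize q to 0.1, and
average per-bead bin means across beads; only beads the cell passed
essentially fully over are informative (partial transits normalize to
their own noise floor). Kernel-density weights within each positional bin
are provided for plotting the point cloud under the profile line.

## Colocalization

Pearson r over the flattened pixels of square ROIs (physical sides round
to the nearest odd pixel count so the ROI has a centre pixel). The negative
control rotates one channel's ROI 90° counterclockwise about the ROI
centre, preserving punctate texture while destroying correspondence; the
direction is irrelevant by symmetry and fixed for reproducibility.
Statistical comparison of r distributions (paired against the rotated
control, unpaired between markers) is delegated to the stats layer.

## Migration statistics

Nucleus tracks (tracker-export CSV or internal tables) are filtered to
those lasting at least half the movie *and* present throughout the first
half, then trimmed to the common first-half window so every lag averages
the same cells. MSD is the ensemble mean of `|x(t) − x(0)|²` (no time
averaging). The persistence ratio is net displacement over *path length*
per window; the printed-formula variant (displacement-from-origin
denominator) is available behind a flag but is not a path length and is
not bounded by 1. The alignment ratio is total distance along the pattern
axis over total distance perpendicular to it, per cell, aggregated per
replicate as the mean of cell ratios; cells with zero perpendicular
distance are excluded with a warning. Confidence bands are percentile
bootstrap over cells (resampling cells with replacement).

## Replicate statistics

Measurements nest raw → cell → technical replicate. Replicate means
default to the pooled mean of the replicate's raw values, with a
cell-mean-of-means mode behind a flag. Classical paired and unpaired
two-tailed t-tests (pooled variance; Welch optional) are computed from
closed forms; no multiple-testing correction is applied and every p-value
is reported with its test metadata.

## What the synthetic scenes do and do not establish

Scenes share the statistical structure of the motivating data — front-born
substrate-fixed puncta with calibrated position statistics, rear-biased
second marker, size-scaled bead signal, heading-biased migration — but are
idealized: elliptical masks, axis-aligned PSF, constant punctum amplitude
(no maturation or bleaching), Poisson+Gaussian camera noise, and no
motion blur, drift or debris. Passing tests therefore demonstrate that the
*algorithms* recover known statistical structure at realistic SNR and
density, not that any specific biological dataset would yield the same
numbers. Sizes used in the validation suite (20 cells × 300 frames for the
position statistics; 100 cells per migration cohort; ~1,000 ROIs for the
rotation null) were chosen so each statistic's sampling error is several
times smaller than the tolerance it is checked against.

## Known limitations

* Calibration targets are jointly infeasible for minimum-gap δ ≥ ~0.04;
  the model family, not the solver, is the limit.
* The detector's cell-edge exclusion band (4 px) discards genuine puncta
  within it (~2% of detection-frames at defaults); widening the band trades
  recall for precision.
* Gap closing assumes stationary targets when bridging; flowing puncta with
  long gaps need a larger `max_displacement`, which weakens the
  event-merging guarantee.
* `find_axis` needs net motion; stalled cells require manual anchors.
* Second-marker placement guarantees non-colocalization only against
  main-marker events, not against other second-marker spots.
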