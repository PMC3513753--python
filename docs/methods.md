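# Methods

## Image model and conventions

Images are 2-D scalar intensity fields with vessels darker than the
background. Coordinates are `(x, y)` with `x` the column index and `y` the
row index increasing downward; pixel centers sit at integer coordinates.
Angles are measured from the +x axis; orientations (tangents of undirected
curves) are reported modulo 180 degrees, folded to `(-90, 90]` degrees.

## Hessian vesselness

Second derivatives are computed by Gaussian smoothing at scale `sigma`
followed by exact central differences (`[1, -2, 1]` and `[0.5, 0, -0.5]`
stencils, reflect boundary). This split is deliberate: sampled
derivative-of-Gaussian kernels carry a small discretization bias (their
discrete sum is not exactly zero), which would leak constant intensity into
the response; with the split form a constant image has exactly zero Hessian
and a quadratic ramp reproduces its analytic second derivative to machine
precision. Derivatives are gamma-normalized (multiplied by `sigma^2`) so
responses at different scales are commensurable and the multi-scale argmax
is well posed.

The blobness ratio is `R_B = |lambda2| / |lambda1|`, which lies in `[0, 1]`
and is near 0 for tubes — the orientation that makes
`exp(-R_B^2/2 beta1^2)` a tube enhancer. The reciprocal ratio is available
behind `VesselnessParams(blobness_ratio="printed")` for experimentation but
suppresses tubes and is not used anywhere. When `lambda1 = 0` the
structureness is zero and the response is defined as 0, so the ratio has no
division hazard. Scale ties in the multi-scale maximum resolve to the
smallest scale. Defaults `beta1 = 1`, `beta2 = 16` suit 8-bit angiographic
contrast: `beta2` is in intensity units and values near 16 ignore
low-contrast clutter while keeping moderate-contrast vessels.

Per-point queries are served from per-scale cached whole-image derivative
fields with bilinear interpolation; the scale set for a query derives from
the current half-width estimate `R` as `{max(1, R/2), 3R/4, R, 5R/4}`
snapped to a 0.25-px grid and clipped to `[1, 10]` px.

## Seed detection

A sparse grid of horizontal and vertical scan lines (default spacing 10 px,
half the minimum accepted segment length) is convolved with the discrete
edge kernel `[1, 2, 0, -2, -1]`. Local extrema of the absolute response
above a robust floor (4x the median absolute response of the line) and
separated by non-maximum suppression (3 px) are boundary candidates, signed
by edge polarity. Consecutive entering/leaving pairs become seeds when the
image gradients at the two walls are anti-parallel within 30 degrees, of
comparable magnitude (ratio in `[0.5, 2]`), and separated by a plausible
vessel width (2–40 px); these three tolerances are engineering choices and
are exposed in the configuration. The seed sits at the pair midpoint with
half-width = separation/2 and direction perpendicular to the local
gradient; a 5x5 check against the center-line map vetoes seeds on
already-traced vessels. Seeds are processed strongest-first (descending
weaker-member response) so high-contrast vessels claim the map first.

## Tracing loop

Each iteration estimates, refines, and advances:

- The semicircular profile spans +-90 degrees about the tracing direction
  at ~1-px arc spacing (`round(pi*r) + 1` samples). Its radius is
  `r = round(rho * max(R^k, R^{k+1}))` with `rho = 1.3`; a constant 5-px
  radius replaces it when the half-width is below 5 px, where rounding
  would collapse the profile onto the vessel wall. Taking the max of the
  adjacent half-widths keeps the profile wide enough across abrupt
  diameter changes (post-stenotic segments).
- Profile maxima must exceed a vesselness floor of 0.05 (noise guard), be
  chord-parallel to the local orientation within 25 degrees, and sit in a
  locally uniform direction field (two neighbors each side within 30
  degrees). The surviving maximum closest in angle to the current direction
  continues the trace; the rest are queued as bifurcation seeds,
  initialized with the parent's half-width and re-estimated from edges on
  their first step.
- Edge refinement walks perpendicular profiles of length `w = r` on both
  sides, scores samples by `|grad x| + |grad y|` of the sigma=1-smoothed
  image, and takes the contrast maximum per side, refined to sub-pixel
  precision with a three-point parabolic fit. The sub-pixel refinement
  matters: integer edge offsets quantize the recentering shift to 0.5 px,
  which alone produces ~3-degree direction kinks at a 5-px step; with the
  fit the orientation error on noiseless straight vessels drops below
  0.5 degrees. The point is recentered midway between the edges and the
  half-width updated to `(eL + eR)/2` (clamped to `[0.75, 20]` px for
  robustness against degenerate edge pairs).
- The step is `alpha = max(1, (1 - omega/pi) R)` where
  `omega = arccos(u^{k-1} . u^k)` is the direction change (0 on the first
  step); the 1-px floor prevents stalls as `omega -> pi`.

Stopping criteria, in order: the profile leaves the image field; no
candidate survives the selection rules; a previously traced pixel appears
on the profile or on the rasterized connection to the next point, in which
case the trace is joined to that segment at the pixel nearest the current
point; the percent dynamic range `gamma = (Sg - B)/B * 100` of the
vesselness across the vessel (signal inside the detected edges, background
beyond them out to `w`) drops to `tau = 0`. When no wall contrast is
detectable at all, the trace also ends with the dynamic-range reason — that
is the flat-background situation the `gamma` stop describes. A safety bound
of 2000 steps per direction exists purely as plumbing.

Traces run both ways from the seed and are concatenated; the pixel chain is
rasterized with 8-connected digital lines. Chains shorter than 20 px are
discarded, as are chains revisiting a pixel left more than 8 chain
positions earlier (self-intersection; the 8-position grace absorbs
sub-pixel rounding without tolerating genuine loops). Accepted chains are
written into the center-line map under a fresh segment number; already
labeled pixels are never relabeled.

## Synthetic phantoms

Center-lines are chains of constant-curvature arcs (closed-form position
and tangent, C1-continuous joints, 1-px arc-length sampling; the zero-
curvature limit is handled analytically). The half-width profile is a
linear taper multiplied by one raised-cosine bump per lesion — the bump has
compact support, apex value exactly equal to the prescribed percent
diameter stenosis, and an asymmetry parameter that skews rise versus fall
lengths. Rendering projects a circular lumen: intensity
`background - contrast * sqrt(1 - (d/R)^2)` inside the vessel, computed
from nearest-center-line distance (exact to the 1-px sampling); vessel tips
get rounded caps. Noise is additive white Gaussian with
`sigma_n = contrast / 10^(SNR_dB/20)` (amplitude-ratio SNR over the vessel
contrast; a power-ratio definition can be substituted since `sigma_n` is
the only consumer), clipped to `[0, 255]`.

The standard database holds 86 base phantoms in 7 groups — 12 straight/
zero-taper and 7 straight/taper-0.00145 vessels with 30–95% stenosis, 23
knee-type bends (curvature 0.003–0.015 1/px, arc length 50–175 px, taper
0.0008), 9 curved and 9 S-shaped stenosed vessels, and 2x13 multi-segment
vessels with two stenoses at taper 0 and 0.00145 — each rendered noiseless
and at SNR 20, 16, and 10 dB, for 344 images. Default geometry: base
half-width 5 px, contrast 100 on background 200, lesion extent 40 px.
Within the published group structure the individual stenosis percentages,
curvature/length grids, and lesion pairings are this package's choices,
spread uniformly over the stated ranges.

What the phantoms do *not* emulate: background structures (ribs,
catheters, diaphragm gradients), vessel crossings and overlaps, Poisson
photon statistics, and motion blur. Passing the synthetic suite therefore
demonstrates geometric robustness (stenosis, curvature, taper, additive
noise), not clinical-image performance.

## Evaluation metrics

Distance and orientation errors use perpendicular correspondence: each
reference point is matched where its perpendicular line intersects the
estimated polyline, within a lateral window of 3 local radii; unmatched
points are excluded from the averages (both choices are this package's
reading of the geometric definition). `dNorm = mean(d_i^2 / r_i^2)`
emphasizes errors where the vessel is thin. Orientation error is reported
both as mean square (degrees^2) and its root; claims of the form "below one
degree" are checked against the RMSE. Point-set measures (discrepancy,
consistency pair, F1, coverage) use strict delta-disk nearest-neighbor
correspondence; discrepancy and F1 default to delta = 5 px, while coverage
inside the success rate uses a stricter delta = 2 px against the rasterized
center-line map (the map, not the sparse trace points, is the algorithm's
output). Coverage below 60% counts as divergence. The silhouette-based
false-detection measure counts strictly positive vesselness outside the
silhouette and zero vesselness inside, normalized by twice the pixel count.

## Problem sizes and determinism

The acceptance script traces the 19 noiseless group-1/2 phantoms for the
orientation figure and all 86 bases x 10 noise realizations at 20 dB for
the success rate (a few minutes on one CPU). All randomness (noise
realizations) derives from explicit integer seeds; tracing itself is
deterministic, so identical inputs and configuration give byte-identical
output files.

## Known limitations

- Overlapping or crossing vessels are joined rather than disambiguated; no
  dynamic search-window logic is implemented.
- No curve-smoothing post-processing is applied (the sub-pixel recentering
  makes it unnecessary on phantoms, but clinical jitter may differ).
- The seed validation rules are a compact reconstruction (anti-parallel
  gradients, magnitude ratio, separation bounds), not a full re-derivation
  of a production seed detector.
- At 10 dB SNR thin vessels (half-width < 3 px) may fail seed validation
  entirely; the tracer then reports no segments rather than guessing.
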