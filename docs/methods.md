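# Methods

## The measurement problem

Dense (calcified) objects such as ureteral stones appear in CT with an
edge smeared by the scanner's point-spread function (PSF). On a display
window (center WC, width WW in Hounsfield units), everything above
WC + WW/2 renders white and everything below WC − WW/2 black. When the
white threshold sits far below the object's attenuation — as in a
soft-tissue window (WC 50, WW 400) — the smeared ramp around the object
is partly supra-threshold and the object *blooms*, measuring larger
than it is. When the threshold sits near the object's peak — e.g. a
high reading inside a bone window (WC 300, WW 1120) — the object
measures smaller. For a symmetric PSF acting on a step edge, the blurred
profile crosses **half** its amplitude exactly at the true edge, so a
zero-width window centered at half the object-to-background attenuation
difference (a *half-value window*) recovers the true outline. That is
the full-width-at-half-maximum (FWHM) principle this package implements
and stress-tests.

Two half-value variants are provided, differing in the attenuation
statistic used: the ROI **mean** (circle as large as possible inside the
stone, to avoid partial-volume contamination) and the ROI **max**
(circle fully enclosing the stone). Since the mean is below the max,
the MEAN window centers lower and measures systematically larger than
the MAX window. The conventional background approximation is 0 HU; it is
a configurable parameter.

## Measurement algorithm

Given a volume and a seed voxel inside the stone:

1. For each reformation plane (axial/coronal/sagittal), tile the volume
   into mean-projection slabs (default 3 mm, half-open intervals
   anchored at the volume face) and pick the slab where the connected
   supra-white region of the soft-tissue window containing the seed has
   maximal area (ties → lowest slab index). "Perceived as largest" is a
   human judgement in practice; maximal apparent area is its
   deterministic surrogate.
2. On the single best image across planes, fit the inner circle
   (largest circle about the region centroid inside the region, minus a
   one-pixel margin; degenerate regions of ≤2 pixels fall back to the
   brightest pixel) and the enclosing circle (largest centroid-to-pixel
   distance plus a one-pixel margin). ROI statistics are computed on raw
   HU of the slab, circle membership strict (<) over pixel centers.
3. Derive the measurement threshold: half the ROI statistic for the
   half-value modes; for soft-tissue/bone modes an explicit perceived
   edge at lower_level + edge_fraction × width (the algorithm cannot
   reproduce a human's visual edge, so the edge location within the
   gray ramp is a parameter — which is precisely the mechanism that
   makes wide windows variable between readers).
4. Threshold each plane's best slab, keep the component at the seed,
   and measure the maximal Feret (caliper) diameter as the largest
   pairwise distance between boundary-pixel centers (convex-hull
   accelerated; exhaustive all-pairs is the test oracle). A single-pixel
   mask measures 0 by convention; boundary pixel centers are used
   without +1-pixel augmentation, so a rasterized disk of radius r
   measures ≈ 2r − 1 pixel.
5. The largest of the three per-plane diameters is the reported size.

`half_value_max_semiauto` composes this with the MAX window and no free
parameters beyond the seed point, the configuration intended for
semi-automated use.

## Phantom simulator

Stones are ellipsoids (so true per-axis diameters 2·semi_axes are
analytic) rendered as: indicator sampled on a supersampled grid,
convolved with an isotropic Gaussian PSF parameterized by FWHM
(FWHM = 2√(2 ln 2)·σ), then *averaged over each voxel* (detector-style
partial-volume integration) and optionally degraded with white Gaussian
noise from an explicit seed. Voxel averaging makes the integrated
attenuation mass exactly blur-invariant; rendering is bit-reproducible
from the spec. The 1D profile helper returns the ideal top-hat and its
closed-form erf blur for edge-physics checks.

Numerical notes: for a blurred *ball* the half-amplitude crossing sits
at R − σ²/R (surface curvature), e.g. 2.94 mm instead of 3.00 mm for a
6 mm sphere at 1.0 mm FWHM — an intrinsic limit of the FWHM principle on
curved objects, not an implementation artifact. Thick-slab averaging
shifts the apparent half-max edge further inward (a 3 mm slab of a 6 mm
sphere crosses half-max at ≈5.8 mm); recovery checks therefore use
native-thickness slices to isolate the windowing effect.

## Synthetic cohort

Defaults emulate a proximal-ureteral-stone cohort: largest diameters
lognormal (median 4.8 mm, log-SD 0.35) truncated at 2.0 mm (the usual
inclusion floor), stone attenuation normal (850 ± 150 HU, ≥300 HU) so
apparent maxima land near the ~857 HU reported for such cohorts, mild
axis anisotropy (minor/major ∈ [0.75, 1]), and a fat-like −80 HU
background — the tissue that surrounds a real ureteral stone — while
the half-value protocol keeps its 0 HU background approximation, as it
would on real images. Passage outcomes are Bernoulli with log-odds
4.4 − 0.85·(true diameter), giving ≈55% overall passage at the default
size distribution. PSF FWHM 1.0 mm and noise 15 HU are plausible
low-dose CT values. All of these are emulation choices, not measured
facts; only the ordering and rough magnitudes of downstream statistics
should be read from them.

## Simulated observers

Each observer has fixed traits plus per-reading noise, mapping onto the
two-way random-effects decomposition the agreement statistics assume:

- `edge_fraction` ∈ [0,1]: where in the gray ramp the observer reads the
  border (wide windows only). A fixed spread of this trait produces a
  threshold spread proportional to WW — 1120 HU in the bone window vs
  400 HU in soft tissue — which is the mechanism behind the bone
  window's large interreader variability.
- `roi_center_sd` (mm): histogram-circle placement jitter. The inner
  (mean) circle is displaced as drawn, picking up partial-volume border
  pixels; the enclosing (max) circle is re-drawn about the displaced
  center but still must fully include the stone, so the max read-out is
  placement-insensitive — reproducing why the MAX variant is the most
  reproducible.
- `caliper_sd` (mm): caliper jitter added independently per in-plane
  measurement (so the largest-of-three invariant holds exactly).

Default panel (edge fractions 0.30/0.45/0.50/0.55/0.70, caliper 0.10 mm,
ROI jitter 0.5 mm) is a calibration choice tuned so the simulated
per-window variability ranks and roughly sizes like a heterogeneous
human panel; it is not behavioral data. ROI placement jitter is clamped to the
inner-circle radius (a circle drawn clear off the stone would simply be
re-placed), and a displaced placement that still shows no stone
contrast falls back to the nominal one. All randomness flows through
per-(stone, observer, window) substreams of a master seed, so tables
regenerate bit-exactly and are invariant to loop order.

A small, low-attenuation stone can be genuinely invisible under
thick-slab partial volume (its 3 mm slab average never reaches the
soft-tissue white level); such stones are logged and excluded from the
study table, observer-independently, so per-window tables stay
balanced.

What the simulation does *not* model: reading order and learning
effects, anatomy (ureter, phleboliths, adjacent bone), scanner-specific
kernels, beam hardening, or human perception beyond the threshold
mechanism. Passing tests show the algorithms behave as designed under
the stated mechanisms — they do not re-derive clinical agreement values,
which depend on real readers and real images.

## Agreement statistics (LOAM)

Model: y_ij = μ + a_i + b_j + e_ij with independent zero-mean subject,
observer and residual effects. The deviation of one observer from the
per-subject mean of all m observers has variance
(1 − 1/m)(σ_B² + σ_E²), and

LOAM = z_{(1+level)/2} · sqrt((1 − 1/m)(σ_B² + σ_E²)),

reported as ±LOAM (default level 0.95). Components come from the
balanced two-way ANOVA moment estimators (negative estimates truncated
at 0 with a warning) or, for unbalanced tables such as an excluded
observer-window cell, from REML on the full Gaussian likelihood
(Nelder–Mead on log-variances).

Confidence interval: a modified-large-sample (Graybill–Wang) two-sided
interval on θ = σ_B² + σ_E² — a positive combination MS_B/n +
(1 − 1/n)·MS_E of independent mean squares — mapped through the LOAM
formula; unbalanced tables use a parametric bootstrap (percentile,
clamped to bracket the point estimate). The construction is validated by
coverage simulation (≈95–97% at n=124, m=5), not by formula identity
with any particular reference implementation. The plug-in LOAM point
estimate carries the usual delta-method square-root bias
E[√t] ≈ √θ·(1 − Var(t)/8θ²), about −1.6% at n=124, m=5; tests account
for it explicitly rather than hiding it in loose tolerances.

## Passage model

Plain maximum-likelihood logistic regression of the binary passage
outcome on measured size, fitted by Fisher scoring (step-damped; score
tolerance 1e−8, ≤50 iterations). Complete separation is detected (all
fitted probabilities numerically 0/1, or diverging coefficients) and
surfaced as an unconverged fit — no penalization, because a shrunken
slope would change what the prediction curves mean. `size_at_prob`
inverts the curve exactly; per-(observer, window) curve families report
failed groups instead of dropping them.

## Problem sizes and runtime choices

The demo and recomputation scripts use 24–40 stones at 0.5 mm voxels
with 5 observers × 4 windows, and 300–500 Monte-Carlo replicates for
estimator validation — sizes chosen so a full desk reproduction runs in
seconds while leaving the Monte-Carlo error small relative to the
effects examined. The high-resolution recovery phantom uses 0.2 mm
voxels with 3× supersampling.

## Known limitations

- Ellipsoid phantoms with Gaussian PSF; no realistic stone morphology,
  spectral physics, or reconstruction-kernel modeling.
- The perceived-edge model is a single threshold parameter; real visual
  segmentation is richer.
- The ≥-at-center convention for zero-width windows (a voxel exactly at
  half-max counts as stone) is this package's choice; clinical viewers
  do not document their boundary behavior.
- Clinical LOAM values and CI endpoints from reader studies are not
  reproducible from simulation; only their ordering and mechanism are.
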