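# Methods

This note records the models and procedures `frondshape` implements, the
conventions it fixes where the method leaves room, and what the synthetic
generators do and do not emulate.

## Outline extraction

An input image is a single flattened frond photographed on a pale,
contrasting background.  The chain is:

1. **Threshold** the inverse blue channel (255 − B) with Otsu's criterion
   on a 256-bin histogram; pixels *strictly above* the threshold are
   foreground.  Plant tissue is low-blue, so the inverse is bimodal with
   the frond in the upper mode.  A constant channel raises a
   degenerate-input error.
2. **Components**: connected components use 4-connectivity; only the
   largest (by pixel count) is kept.  Size ties are broken by the
   component containing the lexicographically smallest (row, col) pixel.
3. **Holes** are filled by flood fill, so the background becomes a single
   border-connected region.
4. **Boundary tracing**: a boundary pixel is a foreground pixel
   4-adjacent to at least one background pixel (the image border counts
   as background; masks touching the border are implicitly padded).  The
   adjacency sense is a convention choice; 4-adjacency matches the
   connectivity used for components, and Moore-neighbor contour following
   with Jacob's stopping criterion then visits exactly this set for
   hole-free regions.  Traversal starts at the topmost-then-leftmost
   boundary pixel and proceeds clockwise on screen; pixels on
   1-pixel-wide appendages are reported once, at first visit.  All
   downstream measures are orientation-invariant, so only determinism
   matters.
5. **Resampling**: L equally spaced points (default L = 200) along the
   closed piecewise-linear curve through the trace pixels, starting at
   the first trace pixel, with linear interpolation between pixels.
6. **Normalization**: the reference points are centered on their
   arithmetic mean and scaled so the greatest centroid-to-point distance
   is 1.  The centroid is the mean of the L reference points, not the
   area centroid — the symmetry measure operates on the reference points,
   so their mean is the natural center.  Recentring is part of
   normalization here (the reflection axis is constrained through this
   centroid); size measures are always taken from the pre-normalized
   polygon.

Pixel coordinates are 0-based (row, col) with pixel centers at integer
coordinates; polygon points are (x, y) = (col, row) floats.

## Continuous symmetry measure

For an even-L normalized outline there are exactly L distinct pairings of
reference points, generated by walking clockwise/counterclockwise from a
start location (a start and its antipode induce the same matching): L/2
pairings start between two points (L/2 cross pairs) and L/2 start at a
point (L/2 + 1 pairs, with the start and its antipode self-paired).

For a fixed pairing, the closest mirror-symmetric point set under the
reflection R(t) across the axis at angle t through the centroid assigns,
for each cross pair (i, j), the average q = (R pᵢ + pⱼ)/2 to j and R q to
i (the assignment is identical if j is reflected first, since R is an
involution); self-paired points are projected onto the axis.  The summed
squared distance expands to C·L − (A cos 2t + B sin 2t) with second-moment
sums A, B over the pairs and a pairing-independent constant C, so the
optimal axis is 2t = atan2(B, A) in closed form.  The test suite validates
the closed form against a brute-force oracle (explicit folding over a
3600-step angle grid with golden-section refinement) to better than 1e-7.

Conventions fixed here:

* CSM is reported as the raw mean squared distance in normalized
  coordinates, averaged over all L reference points (self-paired points
  contribute their squared distance to the axis projection once each),
  not multiplied by 100 as in some published variants.
* The axis passes through the centroid of the normalized polygon.
* CSM_forced evaluates only the at-point pairing anchored at the
  reference point farthest from the centroid; ties (relative tolerance
  1e-9) are evaluated exhaustively and the minimum kept.  It bounds CSM
  from above by construction.

CSM and CSM_forced are invariant to rotation and translation exactly and
to scale through the prior normalization.  Reflection symmetry only;
rotational symmetry measures and the decomposition of asymmetry into
fluctuating/directional/antisymmetric components (not identifiable for
outlines without homologous landmarks) are out of scope.

## Morphometrics

Area is the absolute shoelace sum over the L pre-normalized reference
points times calibration²; perimeter the closed sum of edge lengths times
calibration; circularity 4π·area/perimeter², which the isoperimetric
inequality bounds by 1 for simple polygons.  Self-intersecting outlines
are flagged.  The pixel-count mask area is available as a diagnostic
(`mask_area`); the polygon estimate is the primary one.  Calibration
(mm/pixel) is a required user input for absolute units — it is a property
of the imaging rig and cannot be inferred from an image.

## Synthetic fronds

The outline family is an egg curve
(x, y) = s·(1 + p cos t)·(e cos t, sin t) with scale s, elongation
e ≥ 1 and pointiness p ∈ [0, 1): one mirror axis, pointier end (the
farthest point from the centroid) on the axis.  Optional seed-dependent
even harmonics (`jitter`) vary the shape without breaking symmetry.  The
asymmetry knob ε adds a smooth radial bump ε·s·sin²t·(1 + 0.6 cos t) to
one lateral side only: at ε = 0 the dense parameter grid is mirror
symmetric, so the resampled reference points are exactly symmetric as a
point set; for ε > 0 the true asymmetry grows monotonically.
Self-intersection is checked and rejected.

Rendering paints the polygon in a green-ish (low blue) tone on a pale
background so the inverse blue channel is bimodal, then adds Gaussian
pixel noise and seeds small background specks and interior holes to
exercise the cleanup steps.  Renders are flat-shaded: real frond texture,
venation and uneven illumination are *not* emulated, so passing round-trip
tests demonstrate correctness of the geometry chain, not robustness of
Otsu thresholding to natural texture.

Default render/round-trip conditions: 400×400 px canvas, scale 120 px,
noise SD 8 intensity levels, ≤5 specks of ≤2 px radius, ≤3 interior holes
of ≤3 px radius.

## Synthetic cohorts

The cohort generator emulates the study design: 30 parents assigned
403 offspring (13–14 each), detachment ages drawn as distinct days
spanning 1–30 (falling back to continuous ages if a parent needs more
ages than distinct days exist), shelf assigned uniformly at random per
offspring among 4 shelves.  Each response is generated on its analysis
scale as

    y = β₀ + β₁P + β₂P² + β₃P³ + shelf offset + u₀(parent) + u₁(parent)·P + ε

with independent Gaussian random effects and residuals, then
back-transformed (exp for ln-scale responses, 1 − exp for circularity's
ln(1 − x) scale).  Default coefficients qualitatively emulate the
published pattern — size responses (area ~5 mm², perimeter ~9 mm at age
0) rise to a peak near one week of parental age and decline afterwards,
with parent random intercepts (SD 0.5–0.6) and slopes (SD 0.02–0.025)
and residual SDs ~0.55–0.7; shape responses carry weak (circularity,
CSM) or no (CSM_forced) age signal and no parent-level structure, with
small shelf offsets on the responses where the original analysis found
shelf retained.  Exclusion is Bernoulli(logistic(−2.3 + 0.065·P)),
giving ~23% exclusion overall and a clearly positive age trend; excluded
rows carry no measurements.  Random effects are drawn independently per
response, so cross-response correlations (and the geometric constraint
CSM_forced ≥ CSM, which holds for generated *outlines*) are not
reproduced in cohort tables — the tables are statistical, not geometric,
objects.

## Two-stage model selection

Stage 1 compares the three parent random-effects structures (correlated
intercept + slope, intercept, none) for each of the linear, quadratic
and cubic polynomials of parental age (nine candidates, no shelf) fit by
REML, using AICc with n = number of offspring observations.  Mixed fits
use statsmodels `MixedLM`; the "none" structure's REML log-likelihood is
computed in closed form with the unscaled |XᵀX| determinant term, the
convention of `nlme::gls`, which `MixedLM` (whose REML matches
`nlme::lme`) is compared against — this keeps the cross-structure AICc
comparison consistent with the nlme-based protocol the analysis descends
from.  If the winning structure differs across polynomials, the fixed
dredge is run under each winning structure and the structure that also
wins under its own best-fitting polynomial is preferred, tie-broken by
the larger REML ΔAICc margin.  Fits that fail all optimizers (lbfgs,
powell, Nelder–Mead in order, best converged log-likelihood kept) are
retained as non-convergent rows with infinite AICc.

Stage 2 fits the eight fixed-effects candidates (degree 0–3 of P crossed
with shelf, shelf as a 4-level categorical with treatment coding) by ML
— required for comparing fixed structures — and reports the full
AICc-sorted table with ΔAICc and Akaike weights, flagging ΔAICc < 2
alternatives as statistically indistinguishable.  The winner is refit by
REML for reporting and prediction.  The df column counts fixed
coefficients + random-effect (co)variances + residual variance (e.g.,
cubic with intercept + slope effects: 4 + 3 + 1 = 8).

Transforms: ln(x) for CSM and CSM_forced, ln(1 − x) for circularity,
identity for area and perimeter.  Non-positive log arguments (possible
for perfectly symmetric synthetic fronds, impossible in real data) are
floored at half the smallest positive observed value with a warning.

Predictions are population-level (random effects at zero) on a parental
age grid, averaged across shelf levels when shelf is in the model, with
normal-approximation 95% bands from the fixed-effect covariance (delta
method on transformed scales amounts to transforming the band
endpoints, since the transforms are monotone).  Grids beyond the
observed age range trigger an extrapolation warning.  Diagnostics per
fitted response: residual histogram, Q-Q plot, residual-vs-fitted
scatter, and skewness/kurtosis.

## Exclusion models

The binary exclusion indicator is modeled as logistic in parental age
under the same three random structures.  No installed Python package
fits binomial GLMMs by (approximate) maximum likelihood, so the mixed
candidates are fit by a Laplace approximation (per-cluster Newton modes,
joint optimization of fixed effects and the random-effect Cholesky) —
the approximation `lme4::glmer` uses at default settings; the
random-intercept route is cross-checked in the test suite against a
dense Gauss–Hermite quadrature oracle.  The plain-logistic candidate
uses statsmodels GLM.  AICc selects among the three; the selected
model's age-slope Wald z is reported, and the prediction curve maps the
linear predictor ± 1.96 SE through the inverse logit (bands therefore
stay ordered and inside (0, 1)).  Complete separation cannot occur under
the generator's design (both outcomes occur at every age in expectation);
a non-convergent mixed candidate is retained with its flag.

## Verification problem sizes

The acceptance computations use: 100 random polygons per L ∈ {4, 6, 8,
12} against the brute-force CSM oracle (3600-angle grid, golden-section
refinement, agreement < 1e-7); 500 polygons for CSM_forced ≥ CSM; a
20-seed render→extract round trip (CSM within 5e-3, area within 2%);
100 study-scale replicates for cubic-model recovery and 60 for the null
plurality check; 200 replicates for exclusion-slope recovery (within
2 SE) and 1000 plain-logistic replicates for the Wald type-I error
(0.05 ± 0.02).  Replicate counts are chosen so each rate's Monte Carlo
error is small relative to its acceptance margin while the whole battery
stays convenient to run on one CPU.

## Known limitations

* Flat-shaded renders cannot probe Otsu's behavior on real frond texture.
* The Laplace marginal likelihood is an approximation; its error is
  largest for small clusters with large random-effect variance (the
  quadrature cross-check bounds it well below 1 log-likelihood unit at
  the study's cluster sizes).
* Whether the analysis protocol's stage-1 candidates included shelf is
  not determinable from its description; they are fit without shelf here.
* AICc uses n = offspring observations throughout; with random effects
  the effective sample size is smaller, a standard ambiguity of
  information criteria for mixed models.
* Cohort tables emulate statistical structure only (see above); use
  generated outlines/images when geometric consistency matters.
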