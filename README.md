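# frondshape

Outline extraction, bilateral-symmetry quantification and parental-age
cohort statistics for duckweed (*Lemna*) frond morphometrics.

Duckweed parents bud off daughter fronds throughout their lives, and a
long-standing question in plant senescence is whether offspring produced
by older parents are smaller, less circular, or less bilaterally
symmetric.  `frondshape` implements the full measurement-and-analysis
chain for that question:

* **Outline extraction** — from an RGB photograph of a single flattened
  frond on a pale background: Otsu thresholding of the inverse blue
  channel, largest 4-connected component, hole filling, ordered boundary
  tracing (Moore/Pavlidis-style contour following), resampling to
  *L* = 200 equally spaced arc-length reference points, and normalization
  to unit maximal centroid distance.
* **Continuous Symmetry Measure (CSM)** — for an *L*-point normalized
  outline, the minimum over *L* point pairings of the mean squared
  distance between the outline and its *symmetry transform* (the closest
  exactly mirror-symmetric point set, built by reflect–average–reflect
  folding with the analytically optimal axis per pairing):

      CSM = min over pairings, axes of (1/L) Σᵢ ‖pᵢ − p̂ᵢ‖²

  CSM = 0 iff the outline is perfectly bilaterally symmetric.  The
  variant **CSM_forced** anchors the pairing at the outline point farthest
  from the centroid (the frond's pointy tip), so CSM_forced ≥ CSM always.
* **Morphometrics** — area (shoelace), perimeter, and circularity
  4π·area/perimeter² from the pre-normalized reference points, with
  mm-per-pixel calibration.
* **Cohort statistics** — the two-stage AICc protocol: REML comparison of
  parent random-effects structures (intercept + slope / intercept / none)
  over linear–cubic polynomials of parental age *P*, then ML comparison of
  all eight fixed-effects models (degree 0–3 of *P* × presence of shelf
  *S*), reported as a model table (df, logLik, AICc, ΔAICc, Akaike
  weight) with predictions and 95% confidence bands.  Skewed responses
  are transformed first (ln x for CSM and CSM_forced, ln(1 − x) for
  circularity).  A binomial companion models the probability that a frond
  was damaged and excluded as a logistic function of parental age, again
  comparing random structures by AICc.
* **Synthetic generators** — egg-shaped outlines with a tunable asymmetry
  knob (exactly symmetric at zero), noisy rendered images with specks and
  holes, and study-scale cohorts (30 parents × ~13 offspring on 4
  shelves, cubic age trends, parent random intercepts/slopes, and an
  age-dependent exclusion process) so every stage is testable with known
  ground truth.

## Worked example

```python
import frondshape as fs
from frondshape import stats as st

cohort = fs.simulate_cohort(seed=1).table          # 403 offspring, 30 parents
res = st.analyze_response(cohort, "area_mm2")      # two-stage AICc selection
print(res["table"][["model", "df", "logLik", "AICc", "dAICc", "weight"]].head(3))
```

prints

```
    model  df  logLik   AICc  dAICc  weight
      P^3   8 -317.98 652.43   0.00    0.89
  P^3 + S  11 -316.83 656.52   4.09    0.11
      P^2   7 -358.27 730.89  78.46    0.00
```

— the generating cubic model of parental age tops the table with Akaike
weight 0.89 under the parent random intercept + slope structure the
generator used (df = 8 is 4 fixed coefficients + 3 random-effect
(co)variances + 1 residual variance).  Predicted offspring area rises to
a peak of 6.25 mm² at one week of parental age and falls to 3.17 mm² at
day 30.  The exclusion companion selects plain logistic regression and
finds a clearly positive age slope (Wald z = 4.61): daughters of older
parents are more fragile.

The `examples/` directory holds one short narrative script per
capability (symmetry measurement, image round trip, cohort selection,
exclusion modeling); each prints the numbers it computes with a line on
what they mean.  A thin CLI mirrors the pipeline stages:

```
frondshape render   --out imgs --n 5 --seed 1        # synthetic photographs
frondshape measure  --images imgs --out run          # outlines + measures CSV
frondshape simulate --out cohort --seed 1            # synthetic cohort CSV
frondshape analyze  --cohort cohort/cohort.csv --out run
```

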