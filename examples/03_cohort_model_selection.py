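"""Simulate a study-scale cohort and run the two-stage AICc selection.

The cohort emulates the study design — 30 parents on 4 shelves, 403
offspring detaching on days 1-30, offspring area following a cubic
parental-age trend (a peak near one week, decline afterwards) with parent
random intercepts and slopes.  Stage 1 chooses the random structure by
REML AICc; stage 2 ranks all eight fixed-effects models (polynomial degree
of age x presence of shelf) by ML AICc."""

import frondshape as fs
from frondshape import stats as st

cohort = fs.simulate_cohort(seed=1).table
print(f"cohort: {len(cohort)} offspring, {cohort.parent_id.nunique()} parents, "
      f"{cohort.excluded.mean():.1%} excluded\n")

res = st.analyze_response(cohort, "area_mm2")
print("chosen random structure:", res["selection"]["structure"],
      f"({res['selection']['reason']})\n")
cols = ["model", "df", "logLik", "AICc", "dAICc", "weight"]
print(res["table"][cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))

curve = st.predict_with_bands(res["best_fit"], grid=[1, 7, 15, 30])
print("\npredicted offspring area (mm^2) with 95% confidence bands:")
print(curve.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(
    "\nThe generating model (cubic age trend, parent random slopes) tops the\n"
    "table; the prediction peaks near one week of parental age and declines\n"
    "for older parents, the signature the study design encodes."
)
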