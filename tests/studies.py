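"""Replicated simulation studies shared by the acceptance test suite and
the acceptance script.  Each study generates cohorts with the synthetic
generator at the study-design scale (30 parents, 403 offspring, ages on
days 1-30) and measures how often the selection machinery recovers the
generating structure."""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

import frondshape as fs
from frondshape import stats as st

CUBIC_BETA = (5.0, 0.37, -0.033, 0.00062)  # peaks near one week, declines after


def _cohort(rng, response: fs.ResponseParams, excl_beta=(-50.0, 0.0)):
    params = fs.CohortParams(
        responses={"y_resp": response},
        excl_beta=excl_beta,
        seed=int(rng.integers(2**31)),
    )
    return fs.simulate_cohort(params).table


def _two_stage_top_degree(table) -> int:
    data = table.dropna(subset=["y_resp"]).copy()
    data["y"] = data["y_resp"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = st.select_random_structure(data)
        tbl, _ = st.dredge_fixed(data, sel["structure"], refit_best=False)
    return int(tbl.iloc[0]["degree"])


def cubic_selection_study(seed: int, n_reps: int = 100) -> float:
    """Fraction of replicates in which the two-stage AICc selection ranks a
    degree-3 fixed-effects model first, for cohorts generated with a pure
    cubic parental-age effect and parent random intercepts + slopes."""
    rng = np.random.default_rng(seed)
    response = fs.ResponseParams(
        beta=CUBIC_BETA, shelf=(0, 0, 0, 0), re_sd=(0.5, 0.02), resid_sd=0.55
    )
    hits = sum(
        _two_stage_top_degree(_cohort(rng, response)) == 3 for _ in range(n_reps)
    )
    return hits / n_reps


def null_selection_study(seed: int, n_reps: int = 100) -> dict[str, float]:
    """Selection frequencies of each polynomial degree under an
    intercept-only generating model with no parent-level structure."""
    rng = np.random.default_rng(seed)
    response = fs.ResponseParams(
        beta=(5.0, 0.0, 0.0, 0.0), shelf=(0, 0, 0, 0), re_sd=(0.0, 0.0), resid_sd=0.55
    )
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for _ in range(n_reps):
        counts[_two_stage_top_degree(_cohort(rng, response))] += 1
    return {f"degree_{d}": c / n_reps for d, c in counts.items()}


def exclusion_recovery_study(seed: int, n_reps: int = 200) -> float:
    """Fraction of replicates in which the AICc-selected logistic exclusion
    model's age slope lies within 2 SE of the generating slope."""
    rng = np.random.default_rng(seed)
    true_slope = fs.CohortParams().excl_beta[1]
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            params = fs.CohortParams(seed=int(rng.integers(2**31)))
            table = fs.simulate_cohort(params).table
            res = st.fit_exclusion(table)
            f = res["best_fit"]
            se = float(np.sqrt(f.cov_fe[1, 1]))
            if abs(f.fe_params[1] - true_slope) < 2 * se:
                hits += 1
    return hits / n_reps


def exclusion_type1_study(seed: int, n_reps: int = 1000) -> float:
    """Rejection rate of the age-slope Wald test (|z| > 1.96) in the
    logistic exclusion model when the generating slope is zero (exclusion
    probability constant at ~23%)."""
    rng = np.random.default_rng(seed)
    null_beta = (float(np.log(0.23 / 0.77)), 0.0)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            params = fs.CohortParams(excl_beta=null_beta, seed=int(rng.integers(2**31)))
            t = fs.simulate_cohort(params).table
            P = t["parental_age_days"].to_numpy(float)
            X = np.column_stack([np.ones_like(P), P])
            glm = sm.GLM(t["excluded"].to_numpy(float), X, family=sm.families.Binomial()).fit()
            if abs(glm.tvalues[1]) > 1.96:
                rejections += 1
    return rejections / n_reps
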