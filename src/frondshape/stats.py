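"""Cohort statistics: response transforms, two-stage AICc model selection,
exclusion logistic models, predictions with confidence bands, and residual
diagnostics.

The workflow tests how offspring size (area, perimeter) and shape
(circularity, CSM, CSM_forced) depend on parental age ``P`` while
accounting for shelf ``S`` (a 4-level nuisance factor) and non-independence
of offspring sharing a parent:

1. *Random structure.*  For each of the linear, quadratic and cubic
   polynomials of ``P`` (no shelf), fit parent random intercept + slope,
   random intercept, and no random effects by REML and keep the structure
   minimizing AICc; disagreements across polynomials are resolved in favor
   of the structure that also wins under its own best-fitting fixed
   polynomial, tie-broken by the larger REML dAICc margin.
2. *Fixed structure.*  With the chosen random structure, fit all eight
   fixed-effects models (polynomial degree 0-3 of ``P`` crossed with
   presence/absence of ``S``) by maximum likelihood, rank by AICc and
   report the full model table (df, logLik, AICc, dAICc, Akaike weight);
   the winner is refit by REML for reporting and prediction.

Skewed shape responses are transformed first: ``ln(x)`` for CSM and
CSM_forced, ``ln(1 - x)`` for circularity (so high values mean convoluted
shapes).  The binary exclusion (damage) indicator gets the same treatment
with a logistic model of ``P`` under the three random structures.

Gaussian mixed fits use statsmodels ``MixedLM``; its REML log-likelihood
matches ``nlme::lme``, and the closed-form "no random effects" REML
log-likelihood implemented here follows the ``nlme::gls`` convention
(unscaled ``|X'X|`` term) so that the cross-structure AICc comparison
mirrors the nlme-based protocol this analysis descends from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .glmm import LogisticMixedResult, fit_logistic_mixed

RANDOM_STRUCTURES = ("slope", "intercept", "none")
RESPONSE_TRANSFORMS = {
    "area_mm2": "identity",
    "perimeter_mm": "identity",
    "circularity": "log1m",
    "csm": "log",
    "csm_forced": "log",
}


def transform_response(name: str, x: np.ndarray) -> np.ndarray:
    """Analysis-scale transform for a response column.

    ``ln(x)`` for the right-skewed symmetry measures, ``ln(1 - x)`` for the
    left-skewed circularity, identity for size.  Non-positive arguments to
    the log (a perfectly symmetric synthetic frond has CSM = 0) are floored
    at half the smallest positive observed value, with a warning.
    """
    kind = RESPONSE_TRANSFORMS.get(name, "identity")
    x = np.asarray(x, dtype=float)
    if kind == "identity":
        return x
    v = 1.0 - x if kind == "log1m" else x.copy()
    bad = v <= 0
    if bad.any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError(f"no positive values to transform for {name}")
        warnings.warn(
            f"{int(bad.sum())} non-positive value(s) in {name} floored before log",
            stacklevel=2,
        )
        v[bad] = 0.5 * pos.min()
    return np.log(v)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion ``-2 ll + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError("AICc needs n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """Normalized relative likelihoods ``exp(-dAICc/2)``; invariant to a
    constant shift of all AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    w = np.exp(-0.5 * (a - a.min()))
    return w / w.sum()


FIXED_CANDIDATES = [(d, s) for d in (0, 1, 2, 3) for s in (False, True)]


def model_label(degree: int, shelf: bool) -> str:
    if degree == 0:
        return "S" if shelf else "(intercept-only)"
    stem = "P" if degree == 1 else f"P^{degree}"
    return f"{stem} + S" if shelf else stem


def design_matrix(
    P: np.ndarray, shelf: np.ndarray | None, degree: int, include_shelf: bool, n_shelves: int = 4
) -> tuple[np.ndarray, list[str]]:
    """Raw-polynomial design: intercept, P..P^degree, treatment-coded shelf
    dummies."""
    cols = [np.ones_like(P, dtype=float)]
    names = ["intercept"]
    for d in range(1, degree + 1):
        cols.append(P.astype(float) ** d)
        names.append(f"P^{d}" if d > 1 else "P")
    if include_shelf:
        for lev in range(1, n_shelves):
            cols.append((shelf == lev).astype(float))
            names.append(f"shelf[{lev}]")
    return np.column_stack(cols), names


@dataclass
class GaussianFit:
    """One fitted Gaussian candidate (mixed or plain), with everything the
    table, predictions and diagnostics need."""

    fe_params: np.ndarray
    cov_fe: np.ndarray
    llf: float
    k: int  # fixed + variance parameters + residual
    n: int
    converged: bool
    degree: int
    shelf: bool
    random: str
    names: list[str] = field(default_factory=list)
    resid: np.ndarray | None = None
    fitted: np.ndarray | None = None
    p_range: tuple[float, float] = (0.0, 0.0)
    n_shelves: int = 4


def _gls_reml_llf(y: np.ndarray, X: np.ndarray) -> float:
    # nlme::gls convention: unscaled |X'X| determinant term
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    return float(
        -0.5 * ((n - p) * (np.log(2 * np.pi) + 1.0) + (n - p) * np.log(s2))
        - 0.5 * np.linalg.slogdet(X.T @ X)[1]
    )


_MIXEDLM_OPTIMIZERS = ("lbfgs", "powell", "nm")


def _fit_mixedlm(y, X, groups, exog_re, reml):
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for meth in _MIXEDLM_OPTIMIZERS:
            try:
                r = MixedLM(y, X, groups=groups, exog_re=exog_re).fit(
                    reml=reml, method=meth, maxiter=2000
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            if r.converged and (best is None or r.llf > best.llf):
                best = r
            if best is not None and r.converged and meth == "lbfgs":
                break
    return best


def fit_gaussian(
    data: pd.DataFrame,
    degree: int,
    shelf: bool,
    random: str,
    reml: bool,
    n_shelves: int = 4,
) -> GaussianFit:
    """Fit one candidate.  ``data`` needs columns y, parental_age_days,
    shelf, parent_id (rows with missing y already dropped)."""
    P = data["parental_age_days"].to_numpy(float)
    y = data["y"].to_numpy(float)
    X, names = design_matrix(P, data["shelf"].to_numpy(), degree, shelf, n_shelves)
    n, p_fe = X.shape
    prange = (float(P.min()), float(P.max()))
    if random == "none":
        ols = sm.OLS(y, X).fit()
        llf = _gls_reml_llf(y, X) if reml else float(ols.llf)
        return GaussianFit(
            fe_params=np.asarray(ols.params),
            cov_fe=np.asarray(ols.cov_params()),
            llf=llf,
            k=p_fe + 1,
            n=n,
            converged=True,
            degree=degree,
            shelf=shelf,
            random=random,
            names=names,
            resid=np.asarray(ols.resid),
            fitted=np.asarray(ols.fittedvalues),
            p_range=prange,
            n_shelves=n_shelves,
        )
    groups = data["parent_id"].to_numpy()
    if random == "intercept":
        exog_re = np.ones((n, 1))
        k_var = 1
    elif random == "slope":
        exog_re = np.column_stack([np.ones(n), P])
        k_var = 3  # intercept var, slope var, covariance
    else:
        raise ValueError(f"unknown random structure {random!r}")
    r = _fit_mixedlm(y, X, groups, exog_re, reml)
    if r is None:
        return GaussianFit(
            fe_params=np.full(p_fe, np.nan),
            cov_fe=np.full((p_fe, p_fe), np.nan),
            llf=-np.inf,
            k=p_fe + k_var + 1,
            n=n,
            converged=False,
            degree=degree,
            shelf=shelf,
            random=random,
            names=names,
            p_range=prange,
            n_shelves=n_shelves,
        )
    fitted = X @ np.asarray(r.fe_params)
    return GaussianFit(
        fe_params=np.asarray(r.fe_params),
        cov_fe=np.asarray(r.cov_params())[:p_fe, :p_fe],
        llf=float(r.llf),
        k=p_fe + k_var + 1,
        n=n,
        converged=True,
        degree=degree,
        shelf=shelf,
        random=random,
        names=names,
        resid=y - fitted,
        fitted=fitted,
        p_range=prange,
        n_shelves=n_shelves,
    )


def prepare_response(df: pd.DataFrame, response: str) -> pd.DataFrame:
    """Drop rows without measurements and attach the transformed ``y``."""
    d = df.dropna(subset=[response]).copy()
    d["y"] = transform_response(response, d[response].to_numpy())
    return d


def select_random_structure(data: pd.DataFrame, n_shelves: int = 4) -> dict:
    """Stage 1: choose the parent random-effects structure by REML AICc
    over the nine candidates (three structures x linear/quadratic/cubic).

    When the winning structure differs across polynomial degrees, the
    structure that also wins under its own best-fitting fixed polynomial is
    preferred, tie-broken by the larger dAICc margin between best and
    second-best structures.
    """
    table = []
    winners: dict[int, str] = {}
    margins: dict[int, float] = {}
    for degree in (1, 2, 3):
        rows = []
        for random in RANDOM_STRUCTURES:
            f = fit_gaussian(data, degree, False, random, reml=True, n_shelves=n_shelves)
            a = aicc(f.llf, f.k, f.n) if np.isfinite(f.llf) else np.inf
            rows.append((random, a, f.converged))
            table.append({"degree": degree, "random": random, "AICc": a, "converged": f.converged})
        rows.sort(key=lambda r: r[1])
        winners[degree] = rows[0][0]
        margins[degree] = rows[1][1] - rows[0][1]
    distinct = sorted(set(winners.values()), key=RANDOM_STRUCTURES.index)
    if len(distinct) == 1:
        chosen = distinct[0]
        why = "unanimous across polynomials"
    else:
        consistent = []
        for s in distinct:
            tbl, _ = dredge_fixed(data, s, n_shelves=n_shelves, refit_best=False)
            d_best = int(tbl.iloc[0]["degree"])
            if d_best >= 1 and winners[d_best] == s:
                consistent.append(s)
        if len(consistent) == 1:
            chosen = consistent[0]
            why = "wins under its own best-fitting fixed polynomial"
        else:
            pool = consistent if consistent else distinct
            chosen = max(
                pool,
                key=lambda s: max(margins[d] for d, w in winners.items() if w == s),
            )
            why = "largest dAICc margin among structures winning some polynomial"
    return {
        "structure": chosen,
        "winners_by_degree": winners,
        "margins_by_degree": margins,
        "candidates": pd.DataFrame(table),
        "reason": why,
    }


def dredge_fixed(
    data: pd.DataFrame,
    random_structure: str,
    n_shelves: int = 4,
    refit_best: bool = True,
) -> tuple[pd.DataFrame, GaussianFit | None]:
    """Stage 2: ML fits of all eight fixed-effects candidates under the
    chosen random structure; returns the AICc-sorted model table and the
    best model refit by REML (for reporting and prediction)."""
    rows = []
    for degree, shelf in FIXED_CANDIDATES:
        f = fit_gaussian(data, degree, shelf, random_structure, reml=False, n_shelves=n_shelves)
        a = aicc(f.llf, f.k, f.n) if np.isfinite(f.llf) else np.inf
        rows.append(
            {
                "model": model_label(degree, shelf),
                "degree": degree,
                "shelf": shelf,
                "df": f.k,
                "logLik": f.llf,
                "AICc": a,
                "converged": f.converged,
            }
        )
    tbl = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tbl["dAICc"] = tbl["AICc"] - tbl["AICc"].iloc[0]
    tbl["weight"] = akaike_weights(tbl["AICc"].to_numpy())
    tbl["indistinguishable"] = tbl["dAICc"] < 2.0
    best_fit = None
    if refit_best:
        top = tbl.iloc[0]
        best_fit = fit_gaussian(
            data, int(top["degree"]), bool(top["shelf"]), random_structure,
            reml=True, n_shelves=n_shelves,
        )
    return tbl, best_fit


def analyze_response(df: pd.DataFrame, response: str, n_shelves: int = 4) -> dict:
    """Full two-stage protocol for one response; returns the chosen random
    structure, the fixed-effects model table, and the REML-refit winner."""
    data = prepare_response(df, response)
    sel = select_random_structure(data, n_shelves=n_shelves)
    tbl, best = dredge_fixed(data, sel["structure"], n_shelves=n_shelves)
    return {"response": response, "selection": sel, "table": tbl, "best_fit": best, "data": data}


# ---------------------------------------------------------------------------
# exclusion (damage) logistic models


@dataclass
class ExclusionFit:
    fe_params: np.ndarray
    cov_fe: np.ndarray
    llf: float
    k: int
    n: int
    structure: str
    converged: bool

    @property
    def slope_z(self) -> float:
        return float(self.fe_params[1] / np.sqrt(self.cov_fe[1, 1]))


def _fit_exclusion_candidate(y, X, groups, structure: str) -> ExclusionFit:
    n = len(y)
    if structure == "none":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return ExclusionFit(
            np.asarray(glm.params), np.asarray(glm.cov_params()),
            float(glm.llf), X.shape[1], n, structure, True,
        )
    res: LogisticMixedResult = fit_logistic_mixed(
        y, X, groups, structure="intercept" if structure == "intercept" else "slope"
    )
    return ExclusionFit(
        res.fe_params, res.cov_fe, res.llf, res.k_params, n, structure, res.converged
    )


def fit_exclusion(df: pd.DataFrame, grid: np.ndarray | None = None) -> dict:
    """Compare the logistic exclusion-vs-parental-age model under the three
    parent random-effects structures by AICc; returns the model table, the
    selected fit (with Wald z of the age slope) and its prediction curve."""
    y = df["excluded"].to_numpy(float)
    P = df["parental_age_days"].to_numpy(float)
    X = np.column_stack([np.ones_like(P), P])
    groups = df["parent_id"].to_numpy()
    rows = []
    fits = {}
    for structure in RANDOM_STRUCTURES:
        f = _fit_exclusion_candidate(y, X, groups, structure)
        fits[structure] = f
        rows.append(
            {
                "model": {"none": "logistic(P)", "intercept": "logistic(P) + parent intercept",
                          "slope": "logistic(P) + parent intercept & slope"}[structure],
                "structure": structure,
                "df": f.k,
                "logLik": f.llf,
                "AICc": aicc(f.llf, f.k, f.n) if np.isfinite(f.llf) else np.inf,
                "converged": f.converged,
            }
        )
    tbl = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tbl["dAICc"] = tbl["AICc"] - tbl["AICc"].iloc[0]
    tbl["weight"] = akaike_weights(tbl["AICc"].to_numpy())
    best = fits[tbl.iloc[0]["structure"]]
    if grid is None:
        grid = np.arange(P.min(), P.max() + 1)
    G = np.column_stack([np.ones_like(grid, dtype=float), grid.astype(float)])
    eta = G @ best.fe_params
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, best.cov_fe, G))
    from scipy.special import expit

    curve = pd.DataFrame(
        {
            "parental_age_days": grid,
            "predicted": expit(eta),
            "lower": expit(eta - 1.96 * se),
            "upper": expit(eta + 1.96 * se),
        }
    )
    return {"table": tbl, "best_fit": best, "curve": curve, "z": best.slope_z}


# ---------------------------------------------------------------------------
# predictions and diagnostics


def predict_with_bands(
    fit: GaussianFit, grid: np.ndarray, average_shelf: bool = True
) -> pd.DataFrame:
    """Population-level predictions (random effects at zero) on a parental
    age grid with normal-approximation 95% confidence bands from the
    fixed-effect covariance; when shelf is in the model the design rows are
    averaged across shelf levels."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.p_range
    if grid.min() < lo or grid.max() > hi:
        warnings.warn("prediction grid extends beyond the observed parental ages", stacklevel=2)
    if fit.shelf and average_shelf:
        levels = np.arange(fit.n_shelves)
        Xs = [
            design_matrix(grid, np.full(grid.shape, lev), fit.degree, True, fit.n_shelves)[0]
            for lev in levels
        ]
        G = np.mean(Xs, axis=0)
    else:
        shelf_col = np.zeros(grid.shape)
        G = design_matrix(grid, shelf_col, fit.degree, fit.shelf, fit.n_shelves)[0]
    eta = G @ fit.fe_params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, fit.cov_fe, G), 0.0))
    return pd.DataFrame(
        {
            "parental_age_days": grid,
            "predicted": eta,
            "lower": eta - 1.96 * se,
            "upper": eta + 1.96 * se,
        }
    )


def residual_diagnostics(fit: GaussianFit, out_dir=None, name: str = "response") -> dict:
    """Histogram, quantile-quantile plot and residual-vs-fitted scatter of a
    fitted model's residuals, plus skewness/kurtosis; returns the summary
    and writes the three PNGs when ``out_dir`` is given."""
    r = fit.resid
    if r is None:
        raise ValueError("fit carries no residuals")
    summary = {
        "skewness": float(sps.skew(r)),
        "kurtosis": float(sps.kurtosis(r)),
        "n": int(len(r)),
    }
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        fig, ax = plt.subplots()
        ax.hist(r, bins=30)
        ax.set_xlabel("residual")
        ax.set_title(f"{name}: residual histogram")
        paths["histogram"] = out / f"{name}_resid_hist.png"
        fig.savefig(paths["histogram"], dpi=100)
        plt.close(fig)

        fig, ax = plt.subplots()
        sps.probplot(r, plot=ax)
        ax.set_title(f"{name}: residual Q-Q")
        paths["qq"] = out / f"{name}_resid_qq.png"
        fig.savefig(paths["qq"], dpi=100)
        plt.close(fig)

        fig, ax = plt.subplots()
        ax.scatter(fit.fitted, r, s=8)
        ax.axhline(0.0, lw=0.8)
        ax.set_xlabel("fitted")
        ax.set_ylabel("residual")
        ax.set_title(f"{name}: residuals vs fitted")
        paths["scatter"] = out / f"{name}_resid_fitted.png"
        fig.savefig(paths["scatter"], dpi=100)
        plt.close(fig)
        summary["plots"] = {k: str(v) for k, v in paths.items()}
    return summary
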