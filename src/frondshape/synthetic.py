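"""Synthetic fronds and synthetic cohorts.

Two generators make every pipeline stage testable without archived raw
data:

* :func:`make_outline` / :func:`render_image` produce egg-shaped, nearly
  bilaterally symmetric outlines (one mirror axis, pointier end on the
  axis — the guitar-pick look of a duckweed frond) and paint them into
  noisy RGB images with specks and interior holes, so segmentation,
  cleanup, tracing and the symmetry measure can be exercised end to end
  with known ground truth.  The ``asymmetry`` parameter adds a smooth bump
  to one lateral side only; at zero the outline is exactly mirror
  symmetric, and the bump grows the true asymmetry monotonically.

* :func:`simulate_cohort` emulates the study design: ~30 parent plants on
  4 shelves, ~400 offspring detaching at known parental ages over days
  1-30, each offspring carrying size/shape responses generated from cubic
  parental-age trends with shelf offsets, parent-level random intercepts
  and slopes, Gaussian residuals, and an age-dependent Bernoulli exclusion
  (damage) process on the logistic scale.

Everything is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import disk, polygon as draw_polygon

from .outline import OutlinePolygon, resample_outline

FROND_RGB = (70, 140, 60)  # low blue: foreground after inverse-blue Otsu
BACKGROUND_RGB = (235, 235, 245)  # pale, high blue


@dataclass(frozen=True)
class FrondShapeParams:
    """Parametric egg-curve frond.

    ``scale`` is the base radius in px; ``elongation`` stretches the
    symmetry axis; ``pointiness`` skews the curve toward one pointy tip on
    the axis; ``asymmetry`` (epsilon) is the amplitude, relative to scale,
    of a smooth bump added to one lateral side only; ``jitter`` adds
    seed-dependent *symmetric* low-order harmonics for shape variety
    without breaking the mirror axis.
    """

    scale: float = 120.0
    elongation: float = 1.3
    pointiness: float = 0.3
    asymmetry: float = 0.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.elongation < 1:
            raise ValueError("scale must be > 0 and elongation >= 1")
        if not 0 <= self.pointiness < 1:
            raise ValueError("pointiness must be in [0, 1)")
        if self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")


def make_outline(params: FrondShapeParams, L: int = 200, n_dense: int = 2048) -> OutlinePolygon:
    """Closed egg-curve outline with ``L`` equal-arc reference points.

    The base curve is ``(x, y) = scale * (1 + p cos t) * (e cos t, sin t)``
    — mirror symmetric about the x axis with its pointier end (the farthest
    point from the centroid) at ``t = 0``.  For ``asymmetry > 0`` a radial
    bump ``eps * scale * sin^2 t * (1 + 0.6 cos t)`` is added on the
    ``sin t > 0`` side only, breaking the symmetry by a smooth, monotone
    amount.  The dense parameter grid is mirror-symmetric, so at
    ``asymmetry = 0`` the resampled reference points are exactly symmetric
    as a point set.
    """
    p = params
    t = 2 * np.pi * np.arange(n_dense) / n_dense
    base = p.scale * (1 + p.pointiness * np.cos(t))
    x = p.elongation * base * np.cos(t)
    y = base * np.sin(t)
    if p.jitter > 0:
        rng = np.random.default_rng(p.seed)
        for k in range(2, 6):
            amp = p.jitter * p.scale * rng.uniform(-1, 1) / k
            r = amp * np.cos(k * t)  # even in t: preserves the mirror axis
            x += r * np.cos(t)
            y += r * np.sin(t)
    if p.asymmetry > 0:
        bump = p.asymmetry * p.scale * np.sin(t) ** 2 * (1 + 0.6 * np.cos(t))
        bump = np.where(np.sin(t) > 0, bump, 0.0)
        norm = np.hypot(x, y)
        x += bump * x / norm
        y += bump * y / norm
    pts = np.column_stack([x, y])
    if not ShapelyPolygon(pts).is_valid:
        raise ValueError("parameters produce a self-intersecting outline")
    # reuse the pipeline resampler; it expects (row, col) order
    return resample_outline(pts[:, ::-1], L=L)


def render_image(
    poly: OutlinePolygon,
    canvas: tuple[int, int] = (400, 400),
    noise_sd: float = 0.0,
    n_specks: int = 0,
    n_holes: int = 0,
    seed: int = 0,
    margin: int = 4,
) -> np.ndarray:
    """Paint an outline into an RGB image that exercises the segmentation
    steps: green-ish frond (low blue) on a pale background so the inverse
    blue channel is bimodal, plus Gaussian intensity noise, background
    specks, and interior holes."""
    H, W = canvas
    rng = np.random.default_rng(seed)
    pts = poly.points - poly.points.mean(axis=0) + np.array([W / 2, H / 2])
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() > W - 1 - margin
        or pts[:, 1].max() > H - 1 - margin
    ):
        raise ValueError("polygon does not fit the canvas with margin")
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(H, W))
    mask[rr, cc] = True

    img = np.empty((H, W, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    img[mask] = FROND_RGB

    if n_holes:
        dist_in = ndimage.distance_transform_edt(mask)
        for _ in range(n_holes):
            r = int(rng.integers(1, 4))
            cand = np.argwhere(dist_in > r + 2)
            if len(cand) == 0:
                continue
            cy, cx = cand[rng.integers(len(cand))]
            rr, cc = disk((cy, cx), r, shape=(H, W))
            img[rr, cc] = BACKGROUND_RGB
    if n_specks:
        dist_out = ndimage.distance_transform_edt(~mask)
        for _ in range(n_specks):
            r = int(rng.integers(1, 3))
            ok = (dist_out > r + 2).copy()
            ok[: margin + r, :] = ok[-margin - r :, :] = False
            ok[:, : margin + r] = ok[:, -margin - r :] = False
            cand = np.argwhere(ok)
            cy, cx = cand[rng.integers(len(cand))]
            rr, cc = disk((cy, cx), r, shape=(H, W))
            img[rr, cc] = FROND_RGB
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ResponseParams:
    """One response's generating model on its analysis scale:
    ``beta`` are the intercept/linear/quadratic/cubic parental-age
    coefficients, ``shelf`` the per-shelf offsets (first is the reference,
    0), ``re_sd`` the parent random intercept and slope SDs, ``resid_sd``
    the residual SD, and ``link`` how the analysis scale maps back to the
    measurement column (identity, ``exp`` for ln-analyzed responses,
    ``one_minus_exp`` for circularity's ln(1 - x) scale)."""

    beta: tuple[float, float, float, float]
    shelf: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    re_sd: tuple[float, float] = (0.0, 0.0)
    resid_sd: float = 0.5
    link: str = "identity"


def _default_responses() -> Mapping[str, ResponseParams]:
    # Qualitative emulation of the study's findings: size responses peak
    # around one week of parental age then decline (cubic, parent random
    # intercept+slope); shape responses carry weak or no age signal and no
    # parent-level structure.
    return {
        "area_mm2": ResponseParams(
            beta=(5.0, 0.37, -0.033, 0.00062),
            shelf=(0.0, 0.15, -0.10, 0.05),
            re_sd=(0.5, 0.02),
            resid_sd=0.55,
        ),
        "perimeter_mm": ResponseParams(
            beta=(9.0, 0.44, -0.040, 0.00075),
            shelf=(0.0, 0.20, -0.12, 0.08),
            re_sd=(0.6, 0.025),
            resid_sd=0.70,
        ),
        "circularity": ResponseParams(
            beta=(-2.55, 0.008, 0.0, 0.0),
            shelf=(0.0, 0.08, -0.05, 0.03),
            resid_sd=0.30,
            link="one_minus_exp",
        ),
        "csm": ResponseParams(
            beta=(-5.6, 0.20, -0.016, 0.00032),
            resid_sd=0.50,
            link="exp",
        ),
        "csm_forced": ResponseParams(
            beta=(-5.1, 0.0, 0.0, 0.0),
            resid_sd=0.55,
            link="exp",
        ),
    }


@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters for a synthetic cohort: 30 parents, 403
    offspring total, 4 shelves, detachment ages on days 1-30, and an
    exclusion (damage) logistic with positive age slope giving ~23%
    exclusion overall."""

    n_parents: int = 30
    n_offspring: int = 403
    n_shelves: int = 4
    age_range: tuple[int, int] = (1, 30)
    responses: Mapping[str, ResponseParams] = field(default_factory=_default_responses)
    excl_beta: tuple[float, float] = (-2.3, 0.065)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCohort:
    """Cohort table plus its generating parameters (the ground truth)."""

    table: pd.DataFrame
    params: CohortParams


def simulate_cohort(params: CohortParams | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw one cohort.

    Each offspring row carries parent id, parental age at detachment
    (strictly increasing within parent), shelf, an exclusion flag drawn
    from ``Bernoulli(logistic(excl_beta0 + excl_beta1 * age))``, and the
    five measurement columns.  Responses are generated on their analysis
    scale as ``beta0 + beta1*P + beta2*P^2 + beta3*P^3 + shelf offset +
    parent intercept + parent slope * P + residual`` and back-transformed;
    excluded fronds (damaged before imaging) have missing measurements.
    """
    p = params if params is not None else CohortParams()
    if seed is not None:
        p = CohortParams(**{**p.__dict__, "seed": seed})
    rng = np.random.default_rng(p.seed)

    base, extra = divmod(p.n_offspring, p.n_parents)
    counts = [base + (1 if i < extra else 0) for i in range(p.n_parents)]
    lo, hi = p.age_range
    rows = []
    for parent in range(p.n_parents):
        n_i = counts[parent]
        if n_i <= hi - lo + 1:
            ages = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_i, replace=False))
        else:  # more daughters than distinct days: continuous detachment times
            ages = np.sort(rng.uniform(lo, hi, size=n_i))
        for a in ages:
            rows.append((parent, float(a), int(rng.integers(p.n_shelves))))
    df = pd.DataFrame(rows, columns=["parent_id", "parental_age_days", "shelf"])
    df.insert(0, "frond_id", [f"f{i:04d}" for i in range(len(df))])

    P = df["parental_age_days"].to_numpy(float)
    shelf = df["shelf"].to_numpy(int)
    parent = df["parent_id"].to_numpy(int)

    eta = p.excl_beta[0] + p.excl_beta[1] * P
    df["excluded"] = rng.random(len(df)) < 1 / (1 + np.exp(-eta))

    for name, rp in p.responses.items():
        b0, b1, b2, b3 = rp.beta
        u_int = rng.normal(0.0, rp.re_sd[0], p.n_parents)
        u_slope = rng.normal(0.0, rp.re_sd[1], p.n_parents)
        shelf_off = np.asarray(rp.shelf)[shelf % len(rp.shelf)]
        y = (
            b0
            + b1 * P
            + b2 * P**2
            + b3 * P**3
            + shelf_off
            + u_int[parent]
            + u_slope[parent] * P
            + rng.normal(0.0, rp.resid_sd, len(df))
        )
        if rp.link == "exp":
            y = np.exp(y)
        elif rp.link == "one_minus_exp":
            y = 1.0 - np.exp(y)
        elif rp.link != "identity":
            raise ValueError(f"unknown link {rp.link!r}")
        df[name] = y

    measure_cols = list(p.responses)
    df.loc[df["excluded"], measure_cols] = np.nan
    return SyntheticCohort(df, p)


def ground_truth_dict(cohort: SyntheticCohort) -> dict:
    """Generating parameters as a JSON-serializable dict."""
    p = cohort.params
    return {
        "n_parents": p.n_parents,
        "n_offspring": p.n_offspring,
        "n_shelves": p.n_shelves,
        "age_range": list(p.age_range),
        "excl_beta": list(p.excl_beta),
        "seed": p.seed,
        "responses": {
            name: {
                "beta": list(rp.beta),
                "shelf": list(rp.shelf),
                "re_sd": list(rp.re_sd),
                "resid_sd": rp.resid_sd,
                "link": rp.link,
            }
            for name, rp in p.responses.items()
        },
    }
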