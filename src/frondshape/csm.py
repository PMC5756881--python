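"""Continuous Symmetry Measure (CSM) of bilateral symmetry for closed
outlines, after Zabrodsky-style folding.

The CSM of an ``L``-point normalized outline is the minimum, over a family
of ``L`` point pairings, of the mean squared distance between the outline
and its *symmetry transform* — the closest exactly mirror-symmetric point
set under that pairing.  It is zero iff the outline is perfectly
bilaterally symmetric, and is dimensionless because the outline is scaled
to unit maximal centroid distance beforehand.

Pairings walk outward from an arbitrary start location, grouping the next
clockwise and counterclockwise not-yet-paired reference points.  With even
``L`` there are exactly ``L`` distinct pairings (a start location and its
antipode induce the same matching): ``L/2`` whose start lies between two
reference points (``L/2`` pairs each) and ``L/2`` whose start *is* a
reference point (``L/2 + 1`` pairs each, the start point and its antipode
being self-paired).

For a fixed pairing the optimal reflection axis through the centroid has a
closed form: writing the reflection across the axis at angle ``t`` as
``R(t)``, each cross pair ``(i, j)`` contributes ``|R p_i - p_j|^2 / 2``
and each self pair ``|p - R p|^2 / 4`` to the summed squared distance,
which expands to ``C·L - (A cos 2t + B sin 2t)`` with second-moment sums
``A, B``; the optimum is at ``2t = atan2(B, A)``.  The closed form is
validated against a dense angle-grid oracle in the test suite.

``csm_forced`` evaluates only the at-point pairing anchored at the
reference point farthest from the centroid — the putative symmetry axis
through the pointy tip of a frond — and therefore always bounds ``csm``
from above.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .outline import NormalizedPolygon


@dataclass(frozen=True)
class Pairing:
    """A perfect matching of reference-point indices induced by a start
    location; ``kind`` is ``"between"`` (start between points ``k`` and
    ``k+1``) or ``"at"`` (start at point ``k``, which is self-paired along
    with the point ``L/2`` away)."""

    pairs: tuple[tuple[int, int], ...]
    kind: str
    k: int

    @property
    def start_descriptor(self) -> str:
        if self.kind == "between":
            return f"between points {self.k},{self.k + 1}"
        return f"at point {self.k}"


@dataclass(frozen=True)
class ReflectionAxis:
    """Reflection axis through ``point`` at ``angle`` radians in [0, pi)."""

    point: np.ndarray
    angle: float


@dataclass(frozen=True)
class CsmResult:
    csm: float
    best_pairing: Pairing
    best_axis: ReflectionAxis
    transform: np.ndarray


def enumerate_pairings(L: int) -> list[Pairing]:
    """All ``L`` distinct pairings of ``L`` reference points (``L`` even).

    Starts ``k`` and ``k + L/2`` induce the same matching, so between-starts
    and at-point starts each contribute ``L/2`` unique pairings.
    """
    if L % 2 or L < 4:
        raise ValueError("pairing enumeration requires even L >= 4")
    out: list[Pairing] = []
    for k in range(L // 2):
        # start between points k and k+1
        pairs = tuple(((k + 1 + t) % L, (k - t) % L) for t in range(L // 2))
        out.append(Pairing(pairs, "between", k))
    for k in range(L // 2):
        # start at point k: k and its antipode are self-paired
        pairs = [(k, k)]
        pairs += [((k + t) % L, (k - t) % L) for t in range(1, L // 2)]
        pairs.append((k + L // 2, k + L // 2))
        out.append(Pairing(tuple(pairs), "at", k))
    return out


@lru_cache(maxsize=8)
def _cached_pairings(L: int) -> tuple[Pairing, ...]:
    return tuple(enumerate_pairings(L))


def _reflection_matrix(angle: float) -> np.ndarray:
    c, s = np.cos(2 * angle), np.sin(2 * angle)
    return np.array([[c, s], [s, -c]])


def _as_points(points: NormalizedPolygon | np.ndarray) -> np.ndarray:
    if isinstance(points, NormalizedPolygon):
        return points.points
    return np.asarray(points, dtype=float)


def _axis_moments(pts: np.ndarray, pairing: Pairing) -> tuple[float, float]:
    idx = np.array(pairing.pairs)
    i, j = idx[:, 0], idx[:, 1]
    cross = i != j
    ic, jc = i[cross], j[cross]
    xi, yi = pts[ic, 0], pts[ic, 1]
    xj, yj = pts[jc, 0], pts[jc, 1]
    A = float(np.sum(xi * xj - yi * yj))
    B = float(np.sum(xi * yj + xj * yi))
    sx, sy = pts[i[~cross], 0], pts[i[~cross], 1]
    A += 0.5 * float(np.sum(sx * sx - sy * sy))
    B += float(np.sum(sx * sy))
    return A, B


def optimal_axis(points: NormalizedPolygon | np.ndarray, pairing: Pairing) -> ReflectionAxis:
    """Closed-form optimal reflection axis (through the centroid) for one
    pairing; minimizer of the pairing's mean squared distance."""
    A, B = _axis_moments(_as_points(points), pairing)
    angle = float(0.5 * np.arctan2(B, A) % np.pi)
    return ReflectionAxis(np.zeros(2), angle)


def symmetry_transform(
    points: NormalizedPolygon | np.ndarray, pairing: Pairing, axis: ReflectionAxis
) -> np.ndarray:
    """Closest exactly mirror-symmetric point set under a pairing and axis.

    For a cross pair ``(i, j)`` one member is reflected across the axis and
    averaged with its mate; the partner point is the reflection of that
    average back across the axis.  (Reflecting ``j`` first instead yields
    the identical assignment, since reflection is an involution.)
    Self-paired points are projected onto the axis.  The result reflects
    onto itself.
    """
    pts = _as_points(points)
    R = _reflection_matrix(axis.angle)
    out = np.empty_like(pts, dtype=float)
    for i, j in pairing.pairs:
        if i == j:
            out[i] = 0.5 * (pts[i] + R @ pts[i])
        else:
            q = 0.5 * (R @ pts[i] + pts[j])
            out[j] = q
            out[i] = R @ q
    return out


def mean_squared_distance(pts: np.ndarray, transform: np.ndarray) -> float:
    """Average squared distance between reference points and their
    counterparts, averaged over all L reference points."""
    d = np.asarray(pts, dtype=float) - transform
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def evaluate_pairing(
    points: NormalizedPolygon | np.ndarray, pairing: Pairing
) -> tuple[float, ReflectionAxis, np.ndarray]:
    """Mean squared distance, optimal axis and symmetry transform for one
    pairing."""
    pts = _as_points(points)
    axis = optimal_axis(pts, pairing)
    tr = symmetry_transform(pts, pairing, axis)
    return mean_squared_distance(pts, tr), axis, tr


def _best_over(points: NormalizedPolygon | np.ndarray, pairings) -> CsmResult:
    pts = _as_points(points)
    L = pts.shape[0]
    # The constant term of the objective is pairing-independent (every point
    # contributes |p|^2 / 2 exactly once), so ranking needs only sqrt(A^2+B^2).
    best_gain = -np.inf
    best_pairing = None
    for pairing in pairings:
        A, B = _axis_moments(pts, pairing)
        gain = np.hypot(A, B)
        if gain > best_gain:
            best_gain = gain
            best_pairing = pairing
    assert best_pairing is not None
    val, axis, tr = evaluate_pairing(pts, best_pairing)
    return CsmResult(max(val, 0.0), best_pairing, axis, tr)


def csm(points: NormalizedPolygon | np.ndarray) -> CsmResult:
    """Continuous Symmetry Measure: minimum mean squared distance to the
    closest bilaterally symmetric polygon over all ``L`` pairings."""
    pts = _as_points(points)
    return _best_over(pts, _cached_pairings(pts.shape[0]))


def csm_forced(points: NormalizedPolygon | np.ndarray, tie_rtol: float = 1e-9) -> CsmResult:
    """CSM restricted to the at-point pairing anchored at the reference
    point farthest from the centroid (ties evaluated exhaustively, minimum
    kept).  Always >= ``csm`` since it minimizes over a subset."""
    pts = _as_points(points)
    L = pts.shape[0]
    if L % 2 or L < 4:
        raise ValueError("csm_forced requires even L >= 4")
    r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    anchors = np.flatnonzero(r >= r.max() * (1 - tie_rtol))
    at = {p.k: p for p in _cached_pairings(L) if p.kind == "at"}
    pairings = {at[int(k) % (L // 2)] for k in anchors}
    return _best_over(pts, pairings)
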