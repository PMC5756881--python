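"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the verbal definition of each
quantity — explicit reflect/average/reflect-back folding over a dense
angle grid with golden-section refinement, literal clockwise /
counterclockwise pair walking, exhaustive flood fill — and deliberately
shares no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def reflect_across(pts: np.ndarray, angle: float) -> np.ndarray:
    """Reflect points across the line through the origin at ``angle``."""
    c, s = np.cos(2 * angle), np.sin(2 * angle)
    R = np.array([[c, s], [s, -c]])
    return pts @ R.T


def walk_pairings(L: int) -> list[list[tuple[int, int]]]:
    """Literal pairing walk: from every start location, repeatedly group the
    next clockwise and counterclockwise not-yet-paired points; unique
    matchings are kept."""
    seen = set()
    out = []
    # between-points starts: first cw point is k+1, first ccw point is k
    for k in range(L):
        cw, ccw = (k + 1) % L, k
        pairs = []
        for t in range(L // 2):
            pairs.append(((cw + t) % L, (ccw - t) % L))
        key = frozenset(frozenset(p) for p in pairs)
        if key not in seen:
            seen.add(key)
            out.append(pairs)
    # at-point starts: the start pairs with itself, then walk outward
    for k in range(L):
        pairs = [(k, k)]
        for t in range(1, L // 2):
            pairs.append(((k + t) % L, (k - t) % L))
        pairs.append(((k + L // 2) % L, (k + L // 2) % L))
        key = frozenset(frozenset(p) for p in pairs)
        if key not in seen:
            seen.add(key)
            out.append(pairs)
    return out


def fold_msd(pts: np.ndarray, pairs, angle: float) -> float:
    """Mean squared distance to the symmetry transform built explicitly:
    reflect one pair member, average with its mate, reflect the average
    back; self-paired points project onto the axis."""
    L = pts.shape[0]
    ref = reflect_across(pts, angle)
    total = 0.0
    for i, j in pairs:
        if i == j:
            proj = 0.5 * (pts[i] + ref[i])
            total += float(np.sum((pts[i] - proj) ** 2))
        else:
            q = 0.5 * (ref[i] + pts[j])
            qi = reflect_across(q[None, :], angle)[0]
            total += float(np.sum((pts[j] - q) ** 2))
            total += float(np.sum((pts[i] - qi) ** 2))
    return total / L


def fold_msd_grid(pts: np.ndarray, pairs, angles: np.ndarray) -> np.ndarray:
    """Vectorized :func:`fold_msd` over an array of candidate angles; the
    same explicit reflect/average/reflect-back construction, evaluated for
    every angle at once."""
    L = pts.shape[0]
    c, s = np.cos(2 * angles), np.sin(2 * angles)  # (A,)
    x, y = pts[:, 0], pts[:, 1]
    rx = c[:, None] * x + s[:, None] * y  # (A, L) reflected coords
    ry = s[:, None] * x - c[:, None] * y
    total = np.zeros_like(angles)
    for i, j in pairs:
        if i == j:
            px = 0.5 * (x[i] + rx[:, i])
            py = 0.5 * (y[i] + ry[:, i])
            total += (x[i] - px) ** 2 + (y[i] - py) ** 2
        else:
            qx = 0.5 * (rx[:, i] + x[j])
            qy = 0.5 * (ry[:, i] + y[j])
            qix = c * qx + s * qy
            qiy = s * qx - c * qy
            total += (x[j] - qx) ** 2 + (y[j] - qy) ** 2
            total += (x[i] - qix) ** 2 + (y[i] - qiy) ** 2
    return total / L


def best_angle_msd(pts: np.ndarray, pairs, n_grid: int = 3600) -> tuple[float, float]:
    """Dense angle grid plus golden-section refinement of the fold
    objective; returns (msd, angle)."""
    grid = np.pi * np.arange(n_grid) / n_grid
    vals = fold_msd_grid(pts, pairs, grid)
    k = int(np.argmin(vals))
    lo = grid[(k - 1) % n_grid]
    hi = lo + 2 * np.pi / n_grid
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = fold_msd(pts, pairs, c), fold_msd(pts, pairs, d)
    while b - a > 1e-12:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = fold_msd(pts, pairs, c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = fold_msd(pts, pairs, d)
    best = min((fc, c), (fd, d))
    return best


def brute_force_csm(pts: np.ndarray, n_grid: int = 3600) -> float:
    """Exhaustive pairings x dense-angle search CSM."""
    return min(best_angle_msd(pts, pairs, n_grid)[0] for pairs in walk_pairings(pts.shape[0]))


def brute_force_csm_forced(pts: np.ndarray, n_grid: int = 3600) -> float:
    """Brute-force CSM restricted to at-point pairings anchored at the
    farthest-from-centroid reference point."""
    L = pts.shape[0]
    r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    anchors = np.flatnonzero(r >= r.max() * (1 - 1e-9))
    best = np.inf
    for k in anchors:
        pairs = [(int(k), int(k))]
        for t in range(1, L // 2):
            pairs.append((int(k + t) % L, int(k - t) % L))
        pairs.append((int(k + L // 2) % L, int(k + L // 2) % L))
        best = min(best, best_angle_msd(pts, pairs, n_grid)[0])
    return best


def brute_force_boundary(mask: np.ndarray) -> set[tuple[int, int]]:
    """Every 1-pixel with at least one 0-pixel among its 4 neighbors
    (image border counts as background)."""
    H, W = mask.shape
    out = set()
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                    out.add((r, c))
                    break
    return out


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components by explicit flood fill."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for yy, xx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                        if 0 <= yy < H and 0 <= xx < W and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(comp)
    return comps


def gh_logistic_intercept_loglik(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, beta: np.ndarray, sd: float, n_nodes: int = 80
) -> float:
    """Marginal loglik of a random-intercept logistic model by dense
    Gauss-Hermite quadrature (oracle for the Laplace fit)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # probabilists' Hermite: integral f(u) phi(u) du = sum w_k/sqrt(2 pi) f(x_k)
    total = 0.0
    eta0 = X @ beta
    for g in np.unique(groups):
        m = groups == g
        contrib = []
        for x, w in zip(nodes, weights):
            eta = eta0[m] + sd * x
            ll = np.sum(y[m] * eta - np.logaddexp(0.0, eta))
            contrib.append(np.log(w) + ll)
        total += np.logaddexp.reduce(contrib) - 0.5 * np.log(2 * np.pi)
    return float(total)
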