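"""Frond outline extraction from single-plant photographs.

The extraction chain converts an RGB image of one flattened frond on a
contrasting background into an ordered, equally spaced, normalized outline
polygon:

1. threshold the *inverse blue channel* with Otsu's criterion,
2. keep the largest 4-connected foreground component,
3. flood-fill interior holes,
4. trace the boundary pixels in order (Moore/Pavlidis-style contour
   following),
5. resample the closed boundary at ``L`` equally spaced arc-length
   reference points,
6. normalize so the greatest centroid-to-point distance is one.

Conventions fixed here and relied on downstream: pixel coordinates are
0-based ``(row, col)`` with pixel centers at integer coordinates; polygon
points are ``(x, y) = (col, row)`` floats; boundary traversal starts at the
topmost-then-leftmost boundary pixel and proceeds counterclockwise in the
``(x, -y)`` frame (clockwise on screen).  All shape measures downstream are
orientation-invariant, so only determinism matters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label


class DegenerateInputError(ValueError):
    """Raised when an image or mask cannot support the requested operation."""


@dataclass(frozen=True)
class OutlinePolygon:
    """Ordered closed polygon of reference points, in pixel units.

    ``points`` is an ``(L, 2)`` float array of ``(x, y)`` coordinates;
    ``calibration`` is mm per pixel (``None`` when only dimensionless shape
    measures are wanted).
    """

    points: np.ndarray
    calibration: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("outline needs an (L, 2) array with L >= 3")
        if self.calibration is not None and not self.calibration > 0:
            raise ValueError("calibration must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def L(self) -> int:
        return self.points.shape[0]

    def with_calibration(self, mm_per_px: float) -> "OutlinePolygon":
        return replace(self, calibration=mm_per_px)


@dataclass(frozen=True)
class NormalizedPolygon:
    """Centroid-at-origin outline scaled so the farthest point is at unit
    distance; the scale- and translation-free input to the symmetry measure."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)

    @property
    def L(self) -> int:
        return self.points.shape[0]


def extract_mask(image: np.ndarray, otsu_bins: int = 256) -> np.ndarray:
    """Threshold the inverse blue channel of an RGB image by Otsu's criterion.

    Returns a boolean mask where True marks the frond (foreground).  The
    frond is painted in low-blue pigment on a pale (high-blue) background,
    so ``255 - blue`` is bimodal with the frond in the upper mode.  Pixels
    strictly above the Otsu threshold are foreground.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB image")
    inv_blue = 255 - image[:, :, 2].astype(np.int64)
    if inv_blue.min() == inv_blue.max():
        raise DegenerateInputError("constant image: no two-class split exists")
    t = threshold_otsu(inv_blue.astype(np.uint8), nbins=otsu_bins)
    return inv_blue > t


def clean_mask(mask: np.ndarray, min_component_pixels: int = 1) -> np.ndarray:
    """Keep the largest 4-connected component and fill interior holes.

    Ties in component size are broken deterministically by the component
    containing the lexicographically smallest ``(row, col)`` pixel.  A
    largest component below ``min_component_pixels`` (segmentation found
    only debris) raises a degenerate-input error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    lab = label(mask, connectivity=1)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    best = counts.max()
    if best < min_component_pixels:
        raise DegenerateInputError(
            f"largest component has {best} px < min_component_pixels={min_component_pixels}"
        )
    tied = np.flatnonzero(counts == best)
    if tied.size == 1:
        keep = tied[0]
    else:
        # first tied label encountered in row-major order owns the smallest
        # (row, col) pixel
        flat = lab.ravel()
        pos = np.isin(flat, tied).argmax()
        keep = flat[pos]
    largest = lab == keep
    return ndimage.binary_fill_holes(largest)


# Moore neighborhood in clockwise screen order (row down): N, NE, E, SE, S, SW, W, NW
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=int,
)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """All 1-pixels 4-adjacent to a 0-pixel (image border counts as 0).

    Adjacency here is the same 4-neighborhood used for connected
    components; this is the defining boundary set that
    :func:`trace_boundary` visits for hole-free blobs.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    interior = ndimage.binary_erosion(padded)[1:-1, 1:-1]  # cross structure
    return np.argwhere(mask & ~interior)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Order the boundary pixels of a cleaned mask by contour following.

    Returns an ``(n, 2)`` integer array of ``(row, col)`` pixels forming a
    closed traversal (each adjacent to the next, last adjacent to first for
    blob-like regions).  Pixels on 1-pixel-wide appendages are reported once,
    at their first visit.  The mask is implicitly padded with background, so
    regions touching the image border are handled.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    p = np.pad(mask, 1)
    start = tuple(np.argwhere(p)[0])  # topmost, then leftmost
    if np.count_nonzero(mask) == 1:
        return np.array([(start[0] - 1, start[1] - 1)])

    # Moore-neighbor tracing with Jacob's stopping criterion. The backtrack
    # starts at the west neighbor of the start pixel, which is background by
    # the row-major scan.
    def scan(cur, back):
        dr, dc = back[0] - cur[0], back[1] - cur[1]
        k0 = _MOORE.tolist().index([dr, dc])
        for step in range(1, 9):
            k = (k0 + step) % 8
            nb = (cur[0] + _MOORE[k, 0], cur[1] + _MOORE[k, 1])
            if p[nb]:
                prev = (cur[0] + _MOORE[(k - 1) % 8, 0], cur[1] + _MOORE[(k - 1) % 8, 1])
                return nb, prev
        return None, None  # isolated pixel; handled above

    back0 = (start[0], start[1] - 1)
    trace = [start]
    cur, back = scan(start, back0)
    first_move = cur
    guard = 4 * p.size
    while guard:
        if cur == start:
            nxt, _ = scan(cur, back)
            if nxt == first_move:  # about to repeat the initial move: closed
                break
        trace.append(cur)
        cur, back = scan(cur, back)
        guard -= 1
    # drop revisits of spur pixels, keeping first occurrence
    seen: set[tuple[int, int]] = set()
    out = []
    for px in trace:
        if px not in seen:
            seen.add(px)
            out.append(px)
    return np.array(out) - 1  # undo padding


def resample_outline(
    trace: np.ndarray, L: int = 200, calibration: float | None = None
) -> OutlinePolygon:
    """Place ``L`` equally spaced reference points along the closed boundary.

    The boundary is the piecewise-linear closed curve through the trace
    pixels in order; reference points are laid at equal arc-length intervals
    starting at the first trace point, interpolating linearly between pixels
    (sub-pixel coordinates are expected).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 3:
        raise DegenerateInputError("trace too short to resample")
    if L < 3:
        raise ValueError("L must be >= 3")
    xy = trace[:, ::-1]  # (row, col) -> (x, y)
    closed = np.vstack([xy, xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise DegenerateInputError("zero-length trace")
    targets = total * np.arange(L) / L
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return OutlinePolygon(np.column_stack([x, y]), calibration=calibration)


def normalize(poly: OutlinePolygon) -> NormalizedPolygon:
    """Center the reference points on their centroid and scale so the
    greatest centroid-to-point distance is one.

    The centroid is the arithmetic mean of the L reference points (the
    symmetry measure operates on the reference points, so their mean is the
    natural center).  Output is invariant to uniform scaling and translation
    of the input.
    """
    pts = poly.points - poly.points.mean(axis=0)
    rmax = np.linalg.norm(pts, axis=1).max()
    if rmax == 0:
        raise DegenerateInputError("all points coincide")
    return NormalizedPolygon(pts / rmax)


def extract_outline(
    image: np.ndarray,
    L: int = 200,
    calibration: float | None = None,
    otsu_bins: int = 256,
    min_component_pixels: int = 1,
) -> tuple[OutlinePolygon, dict]:
    """Run the full image -> outline chain; returns the polygon and a log of
    the cleanup steps (Otsu threshold, components removed, hole pixels filled)."""
    mask = extract_mask(image, otsu_bins=otsu_bins)
    lab = label(mask, connectivity=1)
    n_components = int(lab.max())
    cleaned = clean_mask(mask, min_component_pixels=min_component_pixels)
    largest = np.isin(lab, np.argmax(np.bincount(lab.ravel())[1:]) + 1)
    holes_filled = int(cleaned.sum() - largest.sum())
    inv_blue = 255 - np.asarray(image)[:, :, 2].astype(np.uint8)
    info = {
        "otsu_threshold": int(threshold_otsu(inv_blue, nbins=otsu_bins)),
        "components_removed": n_components - 1,
        "hole_pixels_filled": holes_filled,
        "foreground_pixels": int(cleaned.sum()),
    }
    trace = trace_boundary(cleaned)
    poly = resample_outline(trace, L=L, calibration=calibration)
    return poly, info
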