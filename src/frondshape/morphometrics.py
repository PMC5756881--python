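"""Size and shape descriptors from the pre-normalized outline polygon.

Area and perimeter come from the ``L`` resampled reference points (shoelace
formula and summed edge lengths), converted to absolute units with the
mm-per-pixel calibration; circularity ``4*pi*area/perimeter**2`` is
dimensionless, 1 for a circle and approaching 0 for convoluted outlines.
These run on the *pre*-normalized polygon — normalization deliberately
destroys absolute size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .outline import OutlinePolygon


@dataclass(frozen=True)
class SizeMeasures:
    area: float  # mm^2 (px^2 when no calibration)
    perimeter: float  # mm (px)
    circularity: float
    simple: bool = True  # False when the outline self-intersects


def polygon_area(poly: OutlinePolygon) -> float:
    """Shoelace area of the reference-point polygon, in mm^2 (pixel^2 when
    uncalibrated).  Self-intersecting outlines trigger a warning."""
    pts = poly.points
    x, y = pts[:, 0], pts[:, 1]
    a = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if not _is_simple(pts):
        warnings.warn("self-intersecting outline: shoelace area unreliable", stacklevel=2)
    cal = poly.calibration if poly.calibration is not None else 1.0
    return float(a * cal * cal)


def polygon_perimeter(poly: OutlinePolygon) -> float:
    """Perimeter of the closed reference-point polygon, in mm (px when
    uncalibrated)."""
    pts = poly.points
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cal = poly.calibration if poly.calibration is not None else 1.0
    return float(seg.sum() * cal)


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*area / perimeter**2``; at most 1 for simple polygons
    (isoperimetric inequality)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    return float(4 * np.pi * area / perimeter**2)


def measure(poly: OutlinePolygon) -> SizeMeasures:
    """Area, perimeter and circularity of one outline."""
    simple = _is_simple(poly.points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = polygon_area(poly)
    p = polygon_perimeter(poly)
    return SizeMeasures(a, p, circularity(a, p), simple=simple)


def mask_area(mask: np.ndarray, calibration: float | None = None) -> float:
    """Pixel-count area of a binary mask (diagnostic alternative to the
    polygon estimate)."""
    cal = calibration if calibration is not None else 1.0
    return float(np.count_nonzero(mask) * cal * cal)


def _is_simple(pts: np.ndarray) -> bool:
    return ShapelyPolygon(pts).is_valid
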