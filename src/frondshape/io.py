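"""Reading and writing the pipeline's file formats: 8-bit RGB images
(PNG/TIFF via imageio) and plain-text outline CSVs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .outline import OutlinePolygon


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an H x W x 3 uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img.astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_outline_csv(path, poly: OutlinePolygon) -> None:
    """Outline file: a header comment carrying L and the calibration, then
    ``index,x,y`` rows in pixel units."""
    cal = "" if poly.calibration is None else f"{poly.calibration!r}"
    lines = [f"# L={poly.L} mm_per_px={cal}", "index,x,y"]
    for i, (x, y) in enumerate(poly.points):
        lines.append(f"{i},{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_outline_csv(path) -> OutlinePolygon:
    text = Path(path).read_text().splitlines()
    header = text[0]
    cal: float | None = None
    if header.startswith("#"):
        for tok in header[1:].split():
            if tok.startswith("mm_per_px=") and tok != "mm_per_px=":
                cal = float(tok.split("=", 1)[1])
    pts = [
        (float(x), float(y))
        for _, x, y in (ln.split(",") for ln in text[2:] if ln.strip())
    ]
    return OutlinePolygon(np.array(pts), calibration=cal)
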