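import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def random_star_polygon(rng, L):
    """Random star-shaped polygon, centered and scaled to unit max radius."""
    t = np.sort(rng.uniform(0, 2 * np.pi, L))
    r = rng.uniform(0.4, 1.5, L)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    pts -= pts.mean(axis=0)
    return pts / np.linalg.norm(pts, axis=1).max()


def random_blob(rng, size=40):
    """Random cleaned elliptical blob with bumps, for tracing tests."""
    import frondshape as fs

    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = rng.uniform(size * 0.3, size * 0.7, 2)
    a, b = rng.uniform(3, size * 0.3, 2)
    th = rng.uniform(0, np.pi)
    X = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    Y = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    m = (X / a) ** 2 + (Y / b) ** 2 < 1
    for _ in range(3):
        by, bx = rng.integers(3, size - 3, 2)
        r = int(rng.integers(2, 5))
        if m[by, bx]:
            m |= (yy - by) ** 2 + (xx - bx) ** 2 < r**2
    return fs.clean_mask(m)
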