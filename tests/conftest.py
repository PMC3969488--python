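import numpy as np
import pytest

from ramansizer.core import HyperMap
from ramansizer.phantom import generate, preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A tiny 2x2x3 raw map with an irregular (but monotonic) axis."""
    return HyperMap(
        rng.normal(size=(2, 2, 3)),
        np.array([1600.0, 1604.0, 1608.0]),
        pixel_size=1.0,
    )


def make_cube(rng, rows=3, cols=4, channels=5, pixel_size=1.0):
    wn = 1000.0 + 2.0 * np.arange(channels)
    return HyperMap(rng.normal(size=(rows, cols, channels)), wn, pixel_size)


@pytest.fixture(scope="session")
def ps10_phantom():
    """One thin-axis 10-um phantom area, reused across tests (read-only)."""
    return generate(preset("ps10", seed=42, thin_axis=True))


@pytest.fixture(scope="session")
def phantom_areas():
    """Three analysis areas per standard, thin axis, fixed seeds."""
    out = {}
    for name in ("ps5", "ps10", "ps15"):
        out[name] = [
            generate(preset(name, seed=7000 + 10 * a, thin_axis=True))
            for a in range(3)
        ]
    return out


def flood_fill_labels(mask, connectivity=8):
    """Independent connected-component oracle: iterative flood fill in raster
    order."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((rows, cols), dtype=int)
    current = 0
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < rows and 0 <= xx < cols:
                            if mask[yy, xx] and labels[yy, xx] == 0:
                                labels[yy, xx] = current
                                stack.append((yy, xx))
    return labels
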