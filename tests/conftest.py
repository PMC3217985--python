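from __future__ import annotations

import numpy as np
import pytest

from vesselquant.segment import VesselMask


def make_mask(grid: np.ndarray, pixel_size: float = 1.0) -> VesselMask:
    return VesselMask(np.asarray(grid, dtype=bool), pixel_size=pixel_size)


def plus_skeleton(size: int = 11) -> np.ndarray:
    """Two 9-pixel lines crossing at the centre of a size x size grid."""
    g = np.zeros((size, size), dtype=bool)
    mid = size // 2
    g[mid, mid - 4 : mid + 5] = True
    g[mid - 4 : mid + 5, mid] = True
    return g


def hline(n: int = 10, pad: int = 2) -> np.ndarray:
    g = np.zeros((2 * pad + 1, n + 2 * pad), dtype=bool)
    g[pad, pad : pad + n] = True
    return g


def diag_line(n: int = 10, pad: int = 2) -> np.ndarray:
    g = np.zeros((n + 2 * pad, n + 2 * pad), dtype=bool)
    for i in range(n):
        g[pad + i, pad + i] = True
    return g


def random_masks(n: int, max_side: int = 12, seed: int = 0):
    """Random binary masks up to max_side x max_side, none empty."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        h = int(rng.integers(4, max_side + 1))
        w = int(rng.integers(4, max_side + 1))
        m = rng.random((h, w)) < rng.uniform(0.2, 0.8)
        if m.any():
            out.append(m)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
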