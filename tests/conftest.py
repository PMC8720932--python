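import numpy as np
import pytest

from chromastress.colorspace import ChromaLumImage


@pytest.fixture
def rng():
    return np.random.default_rng(20211220)


@pytest.fixture
def random_rgb(rng):
    """Moderately saturated random sRGB image."""
    return rng.uniform(0.05, 0.95, size=(24, 24, 3))


@pytest.fixture
def random_field(rng):
    """Random chromaticity field (values near the sRGB gamut center)."""
    h, w = 12, 12
    return ChromaLumImage(
        rng.uniform(0.15, 0.3, (h, w)),
        rng.uniform(0.4, 0.55, (h, w)),
        rng.uniform(0.1, 0.9, (h, w)),
    )


def brute_force_heatmap(u, v):
    """Independent oracle: explicit per-pixel loop over the 8-neighborhood."""
    h, w = u.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc, n = 0.0, 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        acc += np.hypot(u[y, x] - u[yy, xx],
                                        v[y, x] - v[yy, xx])
                        n += 1
            out[y, x] = acc / n
    return out
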