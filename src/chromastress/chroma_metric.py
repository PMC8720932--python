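"""The color metric: average local chromaticity difference in (u′, v′).

For each pixel the local chromaticity difference is the mean Euclidean
(u′, v′) distance to its existing 8-connected neighbors — N = 3 at image
corners, N = 5 on borders, N = 8 in the interior.  The image-level metric
is the unweighted mean of this per-pixel quantity over all pixels.  As an
average of distances in a perceptual chromaticity plane, the metric itself
reads as a (dimensionless) distance in that plane; it is 0 iff the
chromaticity field is constant, and independent of the luminance plane.

The full image pipeline mirrors how stimulus rasters are processed:
nearest-neighbor downsampling to 256×256 (skipped when the input is
already that small or when ``resize=False``), sRGB → (u′, v′), then the
neighbor average.
"""

from __future__ import annotations

import numpy as np

from .colorspace import ChromaLumImage, downsample_nearest, rgb_to_chromalum

__all__ = [
    "pair_distance",
    "local_chromaticity_difference",
    "average_chromaticity_difference",
    "heatmap_histogram",
    "METRIC_RESIZE_TO",
]

#: side length stimuli are downsampled to before metric computation
METRIC_RESIZE_TO = 256

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def pair_distance(p, q) -> float:
    """Euclidean distance between two (u′, v′) chromaticities."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite chromaticity coordinates")
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def local_chromaticity_difference(field: ChromaLumImage) -> np.ndarray:
    """Per-pixel mean chromaticity distance to the existing 8-neighbors.

    Returns the H×W heatmap of d_px values.  Images with a degenerate
    dimension (1×K or K×1) are rejected: the neighbor rule assumes a
    two-dimensional grid."""
    u, v = field.u_prime, field.v_prime
    h, w = u.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2×2 for the neighbor rule")
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for dy, dx in _OFFSETS:
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        yn = slice(max(0, dy), h - max(0, -dy))
        xn = slice(max(0, dx), w - max(0, -dx))
        d = np.hypot(u[ys, xs] - u[yn, xn], v[ys, xs] - v[yn, xn])
        total[ys, xs] += d
        count[ys, xs] += 1.0
    return total / count


def average_chromaticity_difference(
    img: np.ndarray, resize: bool = True
) -> float:
    """Image-level color metric for an sRGB raster.

    The image is nearest-neighbor downsampled to 256×256 first unless it
    already fits within that size or ``resize=False`` (patch-level calls
    pass patches that are exactly 256×256 and must not be resized again).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 sRGB array")
    if resize and (
        img.shape[0] > METRIC_RESIZE_TO or img.shape[1] > METRIC_RESIZE_TO
    ):
        img = downsample_nearest(img, METRIC_RESIZE_TO, METRIC_RESIZE_TO)
    field = rgb_to_chromalum(img)
    return float(local_chromaticity_difference(field).mean())


def field_average_difference(field: ChromaLumImage) -> float:
    """Metric evaluated directly on a chromaticity field (no resizing,
    no sRGB round trip).  Used for field-level invariance checks."""
    return float(local_chromaticity_difference(field).mean())


def heatmap_histogram(heatmap: np.ndarray, n_bins: int = 50):
    """Histogram of a local-difference heatmap.

    Returns ``(bin_edges, counts, mean)``; counts sum to the pixel count.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    heatmap = np.asarray(heatmap, dtype=float)
    hi = float(heatmap.max())
    if hi <= 0:
        hi = 1.0  # all-zero heatmap: mass lands in the first bin
    counts, edges = np.histogram(heatmap, bins=n_bins, range=(0.0, hi))
    return edges, counts, float(heatmap.mean())
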