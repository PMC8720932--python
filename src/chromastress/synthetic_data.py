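"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here without any
download: two-color patterns whose metric has a closed form (oracles for
the neighbor-averaging rules), fruit-against-foliage scenes whose
chromaticity difference concentrates on item outlines, corpora of
chromatic noise fields calibrated so the metric distribution matches the
natural-scene reference (mean ≈ 0.0056, SD ≈ 0.0023), and ordinal
discomfort ratings drawn from a linear observer model with per-observer
random intercepts and slopes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .chroma_metric import average_chromaticity_difference
from .colorspace import ChromaLumImage, D65_UV, chromalum_to_rgb, encode_srgb
from .colorspace import _uvl_to_linear_rgb

__all__ = [
    "ObserverModel",
    "make_two_color_image",
    "make_fruit_scene",
    "make_synthetic_corpus",
    "simulate_ratings",
    "one_over_f_texture",
    "NATURAL_MU",
    "NATURAL_SIGMA",
]

#: reference moments of the natural-scene metric distribution the corpus
#: generator targets by default
NATURAL_MU = 0.0056
NATURAL_SIGMA = 0.0023


@dataclass
class ObserverModel:
    """Generative counterpart of the discomfort mixed model.

    Latent rating of observer o for image i:
    ``intercept_o + slope_o · z(metric_i) + ε``, with (intercept_o,
    slope_o) bivariate normal around (intercept, beta) with SDs
    ``sd_intercept``/``sd_slope`` and correlation ``rho_is``, ε Gaussian
    with SD ``sd_noise``.  z(·) standardizes the metric across images.
    The latent value is rounded and clamped to the 1–5 ordinal scale."""

    beta: float = 0.3
    intercept: float = 2.5
    sd_intercept: float = 0.5
    sd_slope: float = 0.2
    rho_is: float = 0.0
    sd_noise: float = 0.7

    def __post_init__(self):
        if min(self.sd_intercept, self.sd_slope, self.sd_noise) < 0:
            raise ValueError("SDs must be non-negative")
        if not -1.0 <= self.rho_is <= 1.0:
            raise ValueError("rho_is must lie in [-1, 1]")


def make_two_color_image(
    color_a, color_b, layout: str = "checkerboard", size: int = 64,
    cell: int = 1,
) -> np.ndarray:
    """Deterministic two-color sRGB pattern.

    Layouts: ``checkerboard`` (cells of side ``cell``), ``stripes``
    (vertical, ``cell`` pixels wide) and ``halves`` (left/right split)."""
    if size < 2:
        raise ValueError("size must be ≥ 2")
    a = np.asarray(color_a, dtype=float)
    b = np.asarray(color_b, dtype=float)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if layout == "checkerboard":
        mask = ((yy // cell) + (xx // cell)) % 2 == 0
    elif layout == "stripes":
        mask = (xx // cell) % 2 == 0
    elif layout == "halves":
        mask = xx < size // 2
    else:
        raise ValueError(f"unknown layout {layout!r}")
    img = np.empty((size, size, 3))
    img[mask] = a
    img[~mask] = b
    return img


def one_over_f_texture(
    size: int, seed: int = 0, alpha: float = 1.0,
    lo: float = 0.15, hi: float = 0.55,
) -> np.ndarray:
    """Luminance plane with a 1/f^α amplitude envelope, rescaled to
    [lo, hi]."""
    rng = np.random.default_rng(seed)
    f = np.hypot(
        np.fft.fftfreq(size)[:, None] * size,
        np.fft.fftfreq(size)[None, :] * size,
    )
    amp = np.zeros_like(f)
    amp[f > 0] = f[f > 0] ** (-alpha)
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    spec = amp * np.exp(1j * phase)
    tex = np.real(np.fft.ifft2(spec))
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)
    return lo + (hi - lo) * tex


def _check_in_gamut(uv, lum_max: float, name: str) -> None:
    lin = _uvl_to_linear_rgb(
        np.array([uv[0]]), np.array([uv[1]]), np.array([lum_max])
    )
    if np.any(lin < -1e-9) or np.any(lin > 1 + 1e-9):
        raise ValueError(f"{name} chromaticity {tuple(uv)} is out of the "
                         f"sRGB gamut at luminance {lum_max}")


def make_fruit_scene(
    bg_chroma=(0.16, 0.55),
    dot_chroma=(0.30, 0.53),
    n_dots: int = 12,
    radius: int = 5,
    size: int = 128,
    seed: int = 0,
    lum_alpha: float = 1.0,
) -> np.ndarray:
    """Scattered chromatic disks ("fruit") on a differently colored
    textured background ("foliage").

    The luminance plane is a 1/f^α texture independent of the chromatic
    layout, so with ``n_dots=0`` the chromaticity field is constant and
    the metric is ≈ 0 despite the luminance structure.  Local
    chromaticity difference concentrates on the disk outlines."""
    if 2 * radius >= size:
        raise ValueError("dots do not fit in the image")
    # foliage scenes are dark: keep luminance low enough that saturated
    # red dot chromaticities remain representable
    lum = one_over_f_texture(size, seed=seed, alpha=lum_alpha,
                             lo=0.10, hi=0.40)
    _check_in_gamut(bg_chroma, float(lum.max()), "background")
    _check_in_gamut(dot_chroma, float(lum.max()), "dot")
    u = np.full((size, size), bg_chroma[0])
    v = np.full((size, size), bg_chroma[1])
    rng = np.random.default_rng(seed + 1)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for _ in range(n_dots):
        cy = rng.integers(radius, size - radius)
        cx = rng.integers(radius, size - radius)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        u[disk] = dot_chroma[0]
        v[disk] = dot_chroma[1]
    return chromalum_to_rgb(ChromaLumImage(u, v, lum))


def fruit_outline_mask(
    n_dots: int, radius: int, size: int, seed: int, width: int = 2
) -> np.ndarray:
    """Dilated boundary mask of the disks drawn by :func:`make_fruit_scene`
    with the same seed (for locating where the heatmap should peak)."""
    rng = np.random.default_rng(seed + 1)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_dots):
        cy = rng.integers(radius, size - radius)
        cx = rng.integers(radius, size - radius)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask |= (r2 <= (radius + width) ** 2) & (
            r2 >= max(radius - width, 0) ** 2
        )
    return mask


def _chroma_noise_image(
    size: int, spread: float, seed: int, lum: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian chromatic noise of the given spread around the white point,
    constant-texture luminance; the metric scales linearly with spread."""
    rng = np.random.default_rng(seed)
    u = D65_UV[0] + spread * rng.standard_normal((size, size))
    v = D65_UV[1] + spread * rng.standard_normal((size, size))
    if lum is None:
        lum = one_over_f_texture(size, seed=seed + 1)
    return chromalum_to_rgb(ChromaLumImage(u, v, lum))


@lru_cache(maxsize=8)
def _spread_lookup(size: int, seed: int):
    """20-point monotone spread → metric lookup for the noise-field family."""
    spreads = np.linspace(0.0, 0.02, 20)
    metrics = np.array(
        [
            average_chromaticity_difference(
                _chroma_noise_image(size, s, seed), resize=False
            )
            for s in spreads
        ]
    )
    return spreads, metrics


def make_synthetic_corpus(
    n_images: int,
    target_mu: float = NATURAL_MU,
    target_sigma: float = NATURAL_SIGMA,
    seed: int = 0,
    size: int = 64,
):
    """Corpus of chromatic noise fields whose metric distribution matches
    a target mean and SD.

    Per-image target metrics are drawn from N(target_mu, target_sigma)
    truncated at a small positive floor, then inverted through the
    spread→metric lookup (linear interpolation).  Returns
    (list of sRGB images, array of realized metric values)."""
    if n_images < 2:
        raise ValueError("need at least 2 images")
    spreads, metrics_lut = _spread_lookup(size, 12345)
    if target_mu + 3 * target_sigma > metrics_lut[-1]:
        raise ValueError("target distribution unreachable with this family")
    rng = np.random.default_rng(seed)
    targets = rng.normal(target_mu, target_sigma, size=n_images)
    targets = np.clip(targets, 0.1 * target_mu, metrics_lut[-1])
    images, realized = [], []
    for i, t in enumerate(targets):
        spread = float(np.interp(t, metrics_lut, spreads))
        img = _chroma_noise_image(
            size, spread, seed=int(rng.integers(0, 2**31 - 1))
        )
        images.append(img)
        realized.append(average_chromaticity_difference(img, resize=False))
    return images, np.asarray(realized)


def simulate_ratings(
    metrics,
    model: ObserverModel | None = None,
    n_observers: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal 1–5 ratings from the linear observer model.

    Returns a long-format table with columns observer_id, image_id,
    rating and the raw metric as covariate column ``metric``."""
    if model is None:
        model = ObserverModel()
    metrics = np.asarray(metrics, dtype=float)
    sd = metrics.std(ddof=1)
    z = (metrics - metrics.mean()) / sd if sd > 0 else np.zeros_like(metrics)
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [model.sd_intercept**2,
             model.rho_is * model.sd_intercept * model.sd_slope],
            [model.rho_is * model.sd_intercept * model.sd_slope,
             model.sd_slope**2],
        ]
    )
    eff = rng.multivariate_normal(
        [model.intercept, model.beta], cov, size=n_observers,
        method="cholesky" if np.linalg.det(cov) > 0 else "svd",
    )
    rows = []
    n_img = metrics.size
    for o in range(n_observers):
        a_o, b_o = eff[o]
        latent = a_o + b_o * z + rng.normal(0, model.sd_noise, size=n_img)
        rating = np.clip(np.rint(latent), 1, 5).astype(int)
        for i in range(n_img):
            rows.append((f"obs{o:03d}", f"img{i:03d}", rating[i], metrics[i]))
    return pd.DataFrame(
        rows, columns=["observer_id", "image_id", "rating", "metric"]
    )
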