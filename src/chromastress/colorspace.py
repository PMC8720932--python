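"""sRGB ↔ CIE XYZ ↔ (u′, v′, L) conversions and nearest-neighbor resizing.

All chromatic computation in this package happens in the CIE 1976 UCS
chromaticity plane (u′, v′), paired with a luminance plane L on the same
scale as CIE Y.  The working RGB space is sRGB with its D65 white point
(IEC 61966-2-1); the reference white is normalized to Y = 1, so luminance
of any sRGB image lies in [0, 1].

Images are plain float64 numpy arrays:

* ``RGBImage``   — H×W×3 gamma-encoded sRGB in [0, 1]
* ``XYZImage``   — H×W×3 linear tristimulus values
* ``ChromaLumImage`` — a small dataclass holding u′, v′ and L planes

The inverse conversion :func:`chromalum_to_rgb` preserves the luminance
plane exactly: chromaticities that fall outside the sRGB gamut are shrunk
toward a pivot chromaticity (default: D65 white) at constant L until the
linear RGB coordinates are representable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

__all__ = [
    "ChromaLumImage",
    "D65_WHITE_XYZ",
    "D65_UV",
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "decode_srgb",
    "encode_srgb",
    "rgb_to_xyz",
    "xyz_to_uvl",
    "rgb_to_chromalum",
    "chromalum_to_rgb",
    "downsample_nearest",
    "load_image",
    "save_image",
]

# IEC 61966-2-1 sRGB primaries with D65 white, Y of white normalized to 1.
SRGB_TO_XYZ = np.array(
    [
        [0.4123907992659595, 0.3575843393838780, 0.1804807884018343],
        [0.2126390058715104, 0.7151686787677559, 0.0721923153607337],
        [0.0193308187155918, 0.1191947797946260, 0.9505321522496606],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

#: XYZ of the D65 reference white (sRGB (1,1,1) through the matrix).
D65_WHITE_XYZ = SRGB_TO_XYZ @ np.ones(3)


def _uv_prime(X, Y, Z, denom_floor=1e-9, white_uv=None):
    """u′ = 4X/(X+15Y+3Z), v′ = 9Y/(X+15Y+3Z); near-black pixels get the
    white-point chromaticity (the ratio is 0/0 at black)."""
    denom = X + 15.0 * Y + 3.0 * Z
    dark = denom < denom_floor
    safe = np.where(dark, 1.0, denom)
    u = 4.0 * X / safe
    v = 9.0 * Y / safe
    if white_uv is None:
        white_uv = D65_UV
    u = np.where(dark, white_uv[0], u)
    v = np.where(dark, white_uv[1], v)
    return u, v


def _white_uv():
    X, Y, Z = D65_WHITE_XYZ
    denom = X + 15.0 * Y + 3.0 * Z
    return np.array([4.0 * X / denom, 9.0 * Y / denom])


#: (u′, v′) chromaticity of D65 — ≈ (0.19784, 0.46832).
D65_UV = _white_uv()


@dataclass
class ChromaLumImage:
    """Per-pixel chromaticity (u′, v′) plus a luminance plane.

    The luminance plane is CIE Y with reference white at 1.  For any image
    derived from sRGB, u′ and v′ lie in [0, 0.7].
    """

    u_prime: np.ndarray
    v_prime: np.ndarray
    lum: np.ndarray

    def __post_init__(self):
        self.u_prime = np.asarray(self.u_prime, dtype=float)
        self.v_prime = np.asarray(self.v_prime, dtype=float)
        self.lum = np.asarray(self.lum, dtype=float)
        if not (self.u_prime.shape == self.v_prime.shape == self.lum.shape):
            raise ValueError("u_prime, v_prime and lum must share a shape")
        if not (
            np.all(np.isfinite(self.u_prime))
            and np.all(np.isfinite(self.v_prime))
            and np.all(np.isfinite(self.lum))
        ):
            raise ValueError("non-finite chromaticity or luminance values")
        if np.any(self.lum < 0):
            raise ValueError("negative luminance")

    @property
    def shape(self):
        return self.lum.shape

    def copy(self) -> "ChromaLumImage":
        return ChromaLumImage(
            self.u_prime.copy(), self.v_prime.copy(), self.lum.copy()
        )


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite sRGB values")
    if img.min() < -1e-12 or img.max() > 1 + 1e-12:
        raise ValueError("sRGB values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def decode_srgb(img: np.ndarray) -> np.ndarray:
    """Gamma-encoded sRGB → linear RGB (IEC 61966-2-1 EOTF), componentwise."""
    img = _validate_rgb(img)
    lin = np.where(
        img <= 0.04045, img / 12.92, ((img + 0.055) / 1.055) ** 2.4
    )
    return lin


def encode_srgb(lin: np.ndarray) -> np.ndarray:
    """Linear RGB in [0,1] → gamma-encoded sRGB (inverse EOTF)."""
    lin = np.clip(np.asarray(lin, dtype=float), 0.0, 1.0)
    return np.where(
        lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1.0 / 2.4) - 0.055
    )


def rgb_to_xyz(img: np.ndarray) -> np.ndarray:
    """Gamma-encoded sRGB image → CIE XYZ (white Y = 1)."""
    return decode_srgb(img) @ SRGB_TO_XYZ.T


def xyz_to_uvl(xyz: np.ndarray) -> ChromaLumImage:
    """XYZ image → (u′, v′, L).  L is the Y channel untouched."""
    xyz = np.asarray(xyz, dtype=float)
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    u, v = _uv_prime(X, Y, Z)
    return ChromaLumImage(u, v, Y.copy())


def rgb_to_chromalum(img: np.ndarray) -> ChromaLumImage:
    """sRGB image → chromaticity planes (u′, v′) + luminance plane."""
    return xyz_to_uvl(rgb_to_xyz(img))


def _uvl_to_linear_rgb(u, v, lum):
    """(u′, v′, L) → linear RGB.  Black (L = 0) maps to (0,0,0)."""
    v_safe = np.where(v < 1e-9, 1.0, v)
    Y = lum
    X = Y * 9.0 * u / (4.0 * v_safe)
    Z = Y * (12.0 - 3.0 * u - 20.0 * v) / (4.0 * v_safe)
    xyz = np.stack([X, Y, Z], axis=-1)
    return xyz @ XYZ_TO_SRGB.T


def chromalum_to_rgb(
    img: ChromaLumImage,
    pivot=None,
    tol: float = 1e-9,
    max_iter: int = 40,
    return_clip_info: bool = False,
):
    """(u′, v′, L) → gamma-encoded sRGB, preserving L exactly.

    Out-of-gamut chromaticities are projected toward ``pivot`` (default the
    D65 white point) at constant luminance: the chromatic vector c − pivot
    is shrunk by binary search until all linear RGB components lie in
    [0, 1].  The hue direction is preserved; the luminance plane is
    reproduced exactly up to encoding quantization.

    With ``return_clip_info=True`` also returns the boolean mask of pixels
    that required projection.
    """
    if pivot is None:
        pivot = D65_UV
    pivot = np.asarray(pivot, dtype=float)
    u, v, lum = img.u_prime, img.v_prime, img.lum
    if np.any(lum > 1 + 1e-9):
        # representable as long as the achromatic axis is: gray at L > 1 is not
        raise ValueError("luminance above the reference white is out of range")

    lin = _uvl_to_linear_rgb(u, v, lum)
    bad = np.any((lin < -tol) | (lin > 1 + tol), axis=-1) & (lum > 0)
    clipped = bad.copy()
    if np.any(bad):
        ub, vb, lb = u[bad], v[bad], lum[bad]
        du, dv = ub - pivot[0], vb - pivot[1]
        lo = np.zeros_like(ub)
        hi = np.ones_like(ub)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            lin_m = _uvl_to_linear_rgb(
                pivot[0] + mid * du, pivot[1] + mid * dv, lb
            )
            ok = np.all((lin_m >= -tol) & (lin_m <= 1 + tol), axis=-1)
            lo = np.where(ok, mid, lo)
            hi = np.where(ok, hi, mid)
        lin[bad] = _uvl_to_linear_rgb(
            pivot[0] + lo * du, pivot[1] + lo * dv, lb
        )
    out = encode_srgb(np.clip(lin, 0.0, 1.0))
    if return_clip_info:
        return out, clipped
    return out


def downsample_nearest(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbor resize: each output pixel copies exactly one input
    pixel, ``src = floor((dst + 0.5) * in / out)`` clamped to range.

    Aspect ratio is deliberately not preserved (a 2844×4284 scene resized
    to 256×256 is a legitimate call)."""
    if out_h < 1 or out_w < 1:
        raise ValueError("target size must be positive")
    img = np.asarray(img)
    in_h, in_w = img.shape[:2]
    rows = np.minimum(
        (np.floor((np.arange(out_h) + 0.5) * in_h / out_h)).astype(int),
        in_h - 1,
    )
    cols = np.minimum(
        (np.floor((np.arange(out_w) + 0.5) * in_w / out_w)).astype(int),
        in_w - 1,
    )
    return img[np.ix_(rows, cols)]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster into an H×W×3 float array in [0, 1].

    8- and 16-bit integer images are normalized by their type maximum;
    grayscale is broadcast to three channels; alpha is dropped with a
    warning."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        warnings.warn(f"{path}: dropping alpha channel")
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def save_image(path, img: np.ndarray) -> None:
    """Write an H×W×3 float image in [0,1] as an 8-bit raster."""
    img = _validate_rgb(img)
    iio.imwrite(path, (np.round(img * 255)).astype(np.uint8))
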