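"""Chromatic rotations and pseudo-rotations at constant luminance.

A transform acts on the (u′, v′) plane only: every pixel chromaticity c is
mapped to ``pivot + s · R(θ) · (c − pivot)``, a rotation by θ about a pivot
chromaticity combined with radial scaling by s ("pseudo-rotation" when
s ≠ 1 — a pure rotation is an isometry of the plane and cannot change the
chromaticity-difference metric, radial scaling multiplies it by s).  The
luminance plane is untouched; the inverse sRGB conversion projects any
out-of-gamut chromaticity toward the pivot at constant luminance.

A deterministic bank of (θ, s) specs supports assembling *triples*: three
transformed versions of one base image whose metric values sit closest to
three target levels (low / medium / high) while sharing the luminance
plane bit-for-bit in (u′, v′, L) space and up to 8-bit quantization after
re-encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chroma_metric import average_chromaticity_difference
from .colorspace import (
    ChromaLumImage,
    D65_UV,
    chromalum_to_rgb,
    rgb_to_chromalum,
)

__all__ = [
    "TransformSpec",
    "Triple",
    "transform_chroma_field",
    "apply_chromatic_transform",
    "generate_transform_bank",
    "build_triples",
    "verify_luminance_preservation",
    "DEFAULT_LEVEL_TARGETS",
]

logger = logging.getLogger(__name__)

#: metric levels used for triples: lower end, mean and higher end of an
#: uncomfortable-stimulus set's metric distribution
DEFAULT_LEVEL_TARGETS = (0.0035, 0.0115, 0.0190)

LEVEL_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class TransformSpec:
    """Rotation angle θ (radians), radial scale s ≥ 0 and pivot (u′, v′)."""

    theta: float
    s: float
    pivot: tuple = (float(D65_UV[0]), float(D65_UV[1]))

    def __post_init__(self):
        if not (0.0 <= self.theta < 2.0 * np.pi):
            raise ValueError("theta must lie in [0, 2π)")
        if not (np.isfinite(self.s) and self.s >= 0):
            raise ValueError("scale must be finite and ≥ 0")

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.s == 1.0


@dataclass
class Triple:
    """Three luminance-matched chromatic variants of one base image."""

    base_id: str
    members: dict  # level name -> sRGB array
    metric_values: dict  # level name -> achieved metric
    specs: dict  # level name -> TransformSpec
    clipped_fraction: dict = field(default_factory=dict)

    def __post_init__(self):
        lv = [self.metric_values[k] for k in LEVEL_NAMES]
        if not (lv[0] < lv[1] < lv[2]):
            raise ValueError("triple levels must be strictly increasing")


def transform_chroma_field(
    fld: ChromaLumImage, spec: TransformSpec
) -> ChromaLumImage:
    """Apply c → pivot + s·R(θ)(c − pivot) to the chromaticity planes."""
    cos_t, sin_t = np.cos(spec.theta), np.sin(spec.theta)
    du = fld.u_prime - spec.pivot[0]
    dv = fld.v_prime - spec.pivot[1]
    u = spec.pivot[0] + spec.s * (cos_t * du - sin_t * dv)
    v = spec.pivot[1] + spec.s * (sin_t * du + cos_t * dv)
    return ChromaLumImage(u, v, fld.lum.copy())


def apply_chromatic_transform(
    img: np.ndarray, spec: TransformSpec, return_clip_info: bool = False
):
    """Transform an sRGB image's chromaticities, preserving luminance.

    Returns the transformed sRGB image; with ``return_clip_info=True``
    also the fraction of pixels whose chromaticity had to be projected
    back into the sRGB gamut."""
    fld = rgb_to_chromalum(img)
    out_field = transform_chroma_field(fld, spec)
    out, clipped = chromalum_to_rgb(
        out_field, pivot=spec.pivot, return_clip_info=True
    )
    if return_clip_info:
        return out, float(clipped.mean())
    return out


def generate_transform_bank(
    n: int = 350,
    theta_steps: int = 35,
    s_range=(0.15, 2.2),
    s_steps: int = 10,
    pivot=None,
):
    """Deterministic grid of (θ, s) specs, truncated to ``n``.

    θ takes ``theta_steps`` equally spaced values in [0, 2π); s takes
    ``s_steps`` values across ``s_range`` with the grid point nearest 1
    snapped to exactly 1, so the identity spec (θ=0, s=1) is always a
    member.  The defaults yield the 350-spec bank used for triple
    generation."""
    lo, hi = s_range
    if not (hi > lo):
        raise ValueError("empty or inverted s_range")
    if theta_steps * s_steps < n:
        raise ValueError("grid smaller than requested bank size")
    if pivot is None:
        pivot = (float(D65_UV[0]), float(D65_UV[1]))
    thetas = np.linspace(0.0, 2.0 * np.pi, theta_steps, endpoint=False)
    scales = np.linspace(lo, hi, s_steps)
    if lo <= 1.0 <= hi:
        scales[np.argmin(np.abs(scales - 1.0))] = 1.0
    specs = [
        TransformSpec(float(t), float(s), tuple(pivot))
        for s in scales
        for t in thetas
    ]
    return specs[:n]


def verify_luminance_preservation(a: np.ndarray, b: np.ndarray) -> float:
    """Max absolute per-pixel luminance difference between two sRGB images."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("images must share dimensions")
    la = rgb_to_chromalum(a).lum
    lb = rgb_to_chromalum(b).lum
    return float(np.max(np.abs(la - lb)))


def build_triples(
    images: dict,
    level_targets=DEFAULT_LEVEL_TARGETS,
    tolerance: float = 0.002,
    bank=None,
    resize: bool = True,
    clip_warn_fraction: float = 0.10,
):
    """Assemble low/medium/high metric triples from a bank of transforms.

    ``images`` maps base_id → sRGB array.  Every spec in the bank is
    applied to each image; for each target level the transform whose
    achieved metric is closest to the target is selected.  Images for
    which any level misses its target by more than ``tolerance`` are
    skipped with a logged reason; only complete triples are returned.
    The procedure is deterministic: no randomness is involved."""
    if bank is None:
        bank = generate_transform_bank()
    if not bank:
        raise ValueError("empty transform bank")
    targets = tuple(level_targets)
    if not (targets[0] < targets[1] < targets[2]):
        raise ValueError("level targets must be strictly increasing")

    triples = []
    for base_id, img in images.items():
        achieved = []
        for spec in bank:
            out, clip_frac = apply_chromatic_transform(
                img, spec, return_clip_info=True
            )
            m = average_chromaticity_difference(out, resize=resize)
            achieved.append((m, spec, out, clip_frac))
        metrics = np.array([a[0] for a in achieved])
        members, mvals, specs, clips = {}, {}, {}, {}
        ok = True
        for name, target in zip(LEVEL_NAMES, targets):
            k = int(np.argmin(np.abs(metrics - target)))
            m, spec, out, clip_frac = achieved[k]
            if abs(m - target) > tolerance:
                logger.info(
                    "%s: no transform within %.4g of %s target %.4g "
                    "(best %.4g)", base_id, tolerance, name, target, m
                )
                ok = False
                break
            if clip_frac > clip_warn_fraction:
                logger.warning(
                    "%s/%s: %.1f%% of pixels gamut-clipped",
                    base_id, name, 100 * clip_frac,
                )
            members[name] = out
            mvals[name] = m
            specs[name] = spec
            clips[name] = clip_frac
        if not ok:
            continue
        if not (mvals["low"] < mvals["medium"] < mvals["high"]):
            logger.info("%s: achieved levels not strictly ordered; skipped",
                        base_id)
            continue
        triples.append(
            Triple(base_id, members, mvals, specs, clips)
        )
    return triples
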