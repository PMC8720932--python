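"""Luminance-domain metrics.

Two scalar summaries of the luminance plane:

* :func:`departure_from_one_over_f` — how far the radial Fourier amplitude
  spectrum departs from the 1/f^α envelope characteristic of natural
  scenes, measured as the RMS residual of a log–log straight-line fit.
  This is a documented approximation of the published
  contrast-sensitivity-weighted discomfort measure, which has no public
  formula; it preserves the construct (deviation from 1/f^α) without
  claiming to reproduce that measure's numbers.
* :func:`luminance_edge_energy` — the chromaticity-difference metric's
  averaging scheme applied to the scalar luminance plane (mean absolute
  8-neighbor luminance difference, same corner/border/interior weights).
  By construction it is exactly invariant under any chromatic transform
  that leaves the luminance plane untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RadialSpectrum",
    "radial_amplitude_spectrum",
    "departure_from_one_over_f",
    "luminance_edge_energy",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class RadialSpectrum:
    """Mean Fourier amplitude per integer radial frequency (cycles/image)."""

    freqs: np.ndarray
    amps: np.ndarray


def radial_amplitude_spectrum(
    lum: np.ndarray, window: bool = False
) -> RadialSpectrum:
    """Radially binned 2-D Fourier amplitude spectrum of a luminance plane.

    The mean is subtracted, the 2-D DFT amplitude is binned by integer
    radial frequency (DC excluded), and bins run from 1 cycle/image to the
    Nyquist frequency of the shorter image side.  An optional raised-cosine
    (Hann) window suppresses wrap-around edge artifacts; it is off by
    default.
    """
    lum = np.asarray(lum, dtype=float)
    h, w = lum.shape
    if h < 8 or w < 8:
        raise ValueError("image too small for a radial spectrum (need ≥ 8×8)")
    x = lum - lum.mean()
    if np.allclose(x, 0.0):
        raise ValueError("zero spectral energy: constant luminance plane")
    if window:
        wy = np.hanning(h)[:, None]
        wx = np.hanning(w)[None, :]
        x = x * wy * wx
        if np.allclose(x, 0.0):
            raise ValueError("zero spectral energy after windowing")
    amp = np.abs(np.fft.fft2(x))
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.hypot(fy[:, None], fx[None, :])
    nyquist = min(h, w) // 2
    bins = np.rint(r).astype(int)
    valid = (bins >= 1) & (bins <= nyquist)
    sums = np.bincount(bins[valid], weights=amp[valid], minlength=nyquist + 1)
    counts = np.bincount(bins[valid], minlength=nyquist + 1)
    freqs = np.arange(1, nyquist + 1, dtype=float)
    amps = sums[1:] / np.maximum(counts[1:], 1)
    keep = counts[1:] > 0
    return RadialSpectrum(freqs[keep], amps[keep])


def departure_from_one_over_f(
    lum: np.ndarray, f_min: float = 2.0, window: bool = False
):
    """RMS departure of the radial amplitude spectrum from a 1/f^α fit.

    Fits log amps = c − α·log f by least squares over radial frequencies
    from ``f_min`` (default 2 cycles/image, excluding the DC-adjacent bin)
    to the Nyquist bin, and returns ``(departure, alpha)`` where departure
    is the root-mean-square residual in log-amplitude units.  Invariant to
    positive rescaling of the luminance plane (absorbed by the intercept).
    """
    spec = radial_amplitude_spectrum(lum, window=window)
    keep = (spec.freqs >= f_min) & (spec.amps > 0)
    f = spec.freqs[keep]
    a = spec.amps[keep]
    if f.size < 3:
        raise ValueError("fewer than 3 radial bins available for the fit")
    lf = np.log(f)
    la = np.log(a)
    design = np.column_stack([np.ones_like(lf), -lf])
    coef, *_ = np.linalg.lstsq(design, la, rcond=None)
    resid = la - design @ coef
    departure = float(np.sqrt(np.mean(resid**2)))
    alpha = float(coef[1])
    return departure, alpha


def luminance_edge_energy(lum: np.ndarray) -> float:
    """Mean absolute 8-neighbor luminance difference (metric border rules).

    Zero iff the luminance plane is constant."""
    lum = np.asarray(lum, dtype=float)
    h, w = lum.shape
    if h < 2 or w < 2:
        raise ValueError("luminance plane must be at least 2×2")
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for dy, dx in _OFFSETS:
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        yn = slice(max(0, dy), h - max(0, -dy))
        xn = slice(max(0, dx), w - max(0, -dx))
        total[ys, xs] += np.abs(lum[ys, xs] - lum[yn, xn])
        count[ys, xs] += 1.0
    return float((total / count).mean())
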