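"""Baseline correction and optional smoothing.

The slowly-varying baseline is estimated as a moving-window minimum envelope
(window proportional to the spectrum length), smoothed with a moving average
of the same width, and subtracted; negative residuals are clamped to zero.
Following the extraction procedure's convention the correction is applied
twice (two passes remove both the raw offset and the small residual the first
pass leaves on sloping baselines); the estimator is pluggable.

Smoothing is off by default — replicate summation already averages noise and
raw peak shapes carry the resolution information — but Savitzky-Golay and
Lowess (locally weighted linear regression with tricube weights) filters are
available.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

from .io import Spectrum

__all__ = ["baseline_correct", "preprocess", "smooth"]


def baseline_correct(s: Spectrum, window_fraction: float = 0.05) -> Spectrum:
    """One baseline-correction pass: subtract the smoothed minimum envelope.

    ``window_fraction`` sets the moving window as a fraction of the number of
    grid points; it must translate to a window no longer than the spectrum.
    Output intensities are clamped at zero.
    """
    n = len(s)
    window = max(3, int(round(window_fraction * n)))
    if window > n:
        raise ValueError(f"baseline window ({window} points) exceeds spectrum length {n}")
    envelope = minimum_filter1d(s.intensity, size=window, mode="nearest")
    envelope = uniform_filter1d(envelope, size=window, mode="nearest")
    corrected = np.maximum(s.intensity - envelope, 0.0)
    return Spectrum(s.mz.copy(), corrected)


def preprocess(s: Spectrum, window_fraction: float = 0.05, passes: int = 2,
               smoothing: str | None = None, **smooth_params) -> Spectrum:
    """Full preprocessing: ``passes`` baseline corrections, then optional smoothing."""
    for _ in range(passes):
        s = baseline_correct(s, window_fraction)
    if smoothing is not None:
        s = smooth(s, smoothing, **smooth_params)
    return s


def smooth(s: Spectrum, method: str = "savitzky_golay", *, window: int = 11,
           order: int = 2, fraction: float = 0.05) -> Spectrum:
    """Smooth the intensity trace; the m/z grid is never changed.

    ``savitzky_golay`` needs an odd ``window`` and polynomial ``order`` <
    window; ``lowess`` fits a tricube-weighted local line over a span of
    ``fraction`` of the points.
    """
    if method == "savitzky_golay":
        if window % 2 == 0 or window < 3:
            raise ValueError("Savitzky-Golay window must be odd and >= 3")
        if order >= window:
            raise ValueError("polynomial order must be smaller than the window")
        if window > len(s):
            raise ValueError("window exceeds spectrum length")
        return Spectrum(s.mz.copy(), savgol_filter(s.intensity, window, order))
    if method == "lowess":
        if not 0 < fraction <= 1:
            raise ValueError("lowess fraction must lie in (0, 1]")
        return Spectrum(s.mz.copy(), _lowess(s.mz, s.intensity, fraction))
    raise ValueError(f"unknown smoothing method {method!r}")


def _lowess(x: np.ndarray, y: np.ndarray, fraction: float) -> np.ndarray:
    """Plain local linear regression with tricube weights (one pass, no robustifying)."""
    n = x.size
    k = max(3, int(round(fraction * n)))
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + k)
        lo = max(0, hi - k)
        xs, ys = x[lo:hi], y[lo:hi]
        d = np.abs(xs - x[i])
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        slope = (w * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (x[i] - xm)
    return out
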