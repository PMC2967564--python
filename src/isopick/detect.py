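"""Peak detection, resolution-power estimation and the intensity threshold.

Candidate isotopic peaks are the local maxima of the *maximal curve*: at each
grid point the maximum of the spectrum over a moving window of width
(m/z)/RP — one resolution element — is taken, and a peak is reported at the
central point of every plateau of that curve (where its derivative passes
from positive to non-positive, ending where it passes from non-negative to
negative).

The effective resolution power RPest is estimated from the data: the
spectrum is split into intervals with equal point counts, the most intense
point of each is treated as the most-likely peak of an ID, and the
monoisotoping fit is run over a grid of RP values around the initial guess;
the RP minimizing the mean fitting score wins.

Noise peaks are removed by a signal-dependent threshold: local-maxima
intensities inside mass windows are modelled as a Gaussian (robust moments)
and the threshold at the window center is mu + 2*sigma, linearly
interpolated across the spectrum.  Window widths are inversely proportional
to a proteome mass-density model, so mass regions dense in real species get
narrower windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ReplicateSet, Spectrum

__all__ = [
    "DetectionParams",
    "Peak",
    "ThresholdCurve",
    "lognormal_mass_density",
    "load_mass_density",
    "maximal_curve",
    "find_peaks",
    "build_threshold",
    "estimate_rp",
]


@dataclass
class DetectionParams:
    """Knobs for detection and RP estimation.

    ``rp_in`` is the user's initial resolution-power guess; ``rp_est`` is
    filled in by :func:`estimate_rp` (and defaults to ``rp_in`` when
    estimation is skipped).  ``rp_grid_bounds`` are multiplicative bounds of
    the log-spaced RP search grid.
    """

    rp_in: float
    z_max: int = 1
    n_intervals: int = 4
    rp_grid_bounds: tuple[float, float] = (0.5, 2.0)
    rp_grid_size: int = 15
    rp_est: float | None = None
    min_window_points: int = 3
    density_file: str | None = None

    def __post_init__(self) -> None:
        if self.rp_in <= 0:
            raise ValueError("rp_in must be positive")
        if self.z_max < 1:
            raise ValueError("z_max must be >= 1")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")

    def rp_grid(self) -> np.ndarray:
        lo, hi = self.rp_grid_bounds
        return self.rp_in * np.logspace(np.log10(lo), np.log10(hi), self.rp_grid_size)


@dataclass
class Peak:
    """A candidate isotopic peak on the representative grid."""

    mz: float
    intensity: float
    grid_index: int


@dataclass
class ThresholdCurve:
    """The mu + 2*sigma noise threshold, interpolated over the grid."""

    centers: np.ndarray
    mus: np.ndarray
    sigmas: np.ndarray
    curve: np.ndarray  # threshold value at every grid point

    @property
    def values(self) -> np.ndarray:
        return self.mus + 2.0 * self.sigmas

    def is_noise(self, peak: Peak) -> bool:
        return peak.intensity < self.curve[peak.grid_index]


def lognormal_mass_density(mass: np.ndarray | float, median: float = 1500.0,
                           shape: float = 1.0) -> np.ndarray | float:
    """Bundled stand-in for a proteome mass histogram: a log-normal density.

    Approximates the mass distribution of detectable peptides/small proteins
    (median ~1.5 kDa, broad shape); replace with a measured two-column
    (mass, density) file for a specific database.
    """
    m = np.maximum(np.asarray(mass, dtype=float), 1e-9)
    return np.exp(-((np.log(m) - np.log(median)) ** 2) / (2 * shape**2)) / m


def load_mass_density(path: str):
    """Load a two-column (mass, density) file; returns an interpolating callable."""
    data = np.loadtxt(path)
    masses, dens = data[:, 0], data[:, 1]
    return lambda m: np.interp(m, masses, dens)


class _RangeMax:
    """Sparse table for O(1) range-maximum queries on a fixed vector."""

    def __init__(self, x: np.ndarray) -> None:
        n = x.size
        levels = max(1, int(np.floor(np.log2(n))) + 1)
        self.table = [np.asarray(x, dtype=float)]
        for k in range(1, levels):
            prev = self.table[-1]
            span = 1 << (k - 1)
            if prev.size <= span:
                break
            self.table.append(np.maximum(prev[:-span], prev[span:]))

    def query(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Vectorized max over inclusive index ranges [lo, hi]."""
        width = hi - lo + 1
        k = np.floor(np.log2(width)).astype(int)
        out = np.empty(lo.size)
        for kk in np.unique(k):
            mask = k == kk
            span = 1 << int(kk)
            t = self.table[int(kk)]
            out[mask] = np.maximum(t[lo[mask]], t[hi[mask] - span + 1])
        return out


def maximal_curve(s: Spectrum, rp: float, min_window_points: int = 3) -> np.ndarray:
    """Moving-window maximum with mass-dependent window width (m/z)/RP."""
    if rp <= 0:
        raise ValueError("resolution power must be positive")
    mz = s.mz
    half = mz / rp / 2.0
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right") - 1
    # enforce a minimum window of min_window_points centred points
    pad = max(0, (min_window_points - 1) // 2)
    idx = np.arange(mz.size)
    lo = np.minimum(lo, np.maximum(idx - pad, 0))
    hi = np.maximum(hi, np.minimum(idx + pad, mz.size - 1))
    return _RangeMax(s.intensity).query(lo, hi)


def find_peaks(rep: Spectrum, rp_est: float, min_window_points: int = 3) -> list[Peak]:
    """Local maxima of the maximal curve, one peak per plateau center.

    Maxima closer than one resolution element (m/z)/RP to a stronger maximum
    are merged into it (they are not separable at this resolution and arise
    from noise micro-plateaus of the maximal curve).  Returned sorted by
    m/z; plateau centers break ties toward lower m/z.
    """
    curve = maximal_curve(rep, rp_est, min_window_points)
    d = np.diff(curve)
    starts = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    ends = np.where((d[:-1] >= 0) & (d[1:] < 0))[0] + 1
    peaks: list[Peak] = []
    j = 0
    for start in starts:
        while j < ends.size and ends[j] < start:
            j += 1
        if j == ends.size:
            break
        # place the peak at the spectrum's apex inside the plateau region:
        # with noise the plateau fragments and its geometric center can sit
        # several grid steps off the apex (ties resolve to lower m/z)
        center = start + int(np.argmax(rep.intensity[start:ends[j] + 1]))
        peaks.append(Peak(float(rep.mz[center]), float(curve[center]), int(center)))
    # merge maxima within one resolution element of a stronger one
    peaks.sort(key=lambda p: (-p.intensity, p.mz))
    kept: list[Peak] = []
    kept_mz: list[float] = []
    for p in peaks:
        radius = p.mz / rp_est
        if kept_mz:
            arr = np.asarray(kept_mz)
            if np.any(np.abs(arr - p.mz) < radius):
                continue
        kept.append(p)
        kept_mz.append(p.mz)
    kept.sort(key=lambda p: p.mz)
    return kept


def build_threshold(peaks: list[Peak], rep: Spectrum, density_model=None,
                    *, min_window_points: int = 200, max_window_fraction: float = 0.10,
                    min_maxima_per_window: int = 5,
                    target_maxima_per_window: int = 100) -> ThresholdCurve:
    """Fit the local-maxima noise Gaussian per window; threshold = mu + 2*sigma.

    Windows tile the spectrum.  The base width is chosen so a window holds
    about ``target_maxima_per_window`` local maxima (enough that the robust
    trim can reject the few maxima belonging to a real isotopic envelope),
    then scaled inversely to the mass density model — mass regions dense in
    real species get narrower, more adaptive windows — and clamped to
    [``min_window_points`` points, ``max_window_fraction`` of the spectrum].
    Windows holding fewer than 5 maxima are merged with their neighbor.  The
    noise Gaussian's (mu, sigma) are estimated robustly as the median and
    1.4826 x MAD of the window's maxima, so real isotopic peaks — which can
    make up a sizeable minority of the maxima in clean spectra — do not
    inflate the threshold.  With fewer than 20 maxima overall a single
    global window is used.
    """
    if density_model is None:
        density_model = lognormal_mass_density
    n = len(rep)
    peak_idx = np.array([p.grid_index for p in peaks], dtype=int)
    peak_int = np.array([p.intensity for p in peaks], dtype=float)

    if peak_idx.size < 20:
        windows = [(0, n)]
    else:
        max_window = max(min_window_points, int(max_window_fraction * n))
        base_width = int(round(n * target_maxima_per_window / peak_idx.size))
        base_width = int(np.clip(base_width, min_window_points, max_window))
        ref_density = float(np.max(np.asarray(density_model(rep.mz))))
        windows = []
        pos = 0
        while pos < n:
            center_guess = rep.mz[min(pos + base_width // 2, n - 1)]
            dens = float(np.asarray(density_model(center_guess)))
            width = base_width if dens <= 0 else \
                int(round(base_width * ref_density / dens))
            width = int(np.clip(width, min_window_points, max_window))
            windows.append((pos, min(pos + width, n)))
            pos += width
        # merge sparse windows into their left neighbor
        merged: list[tuple[int, int]] = []
        for lo, hi in windows:
            count = int(((peak_idx >= lo) & (peak_idx < hi)).sum())
            if merged and (count < min_maxima_per_window):
                merged[-1] = (merged[-1][0], hi)
            else:
                merged.append((lo, hi))
        if len(merged) > 1:
            lo, hi = merged[0]
            if ((peak_idx >= lo) & (peak_idx < hi)).sum() < min_maxima_per_window:
                merged[1] = (lo, merged[1][1])
                merged = merged[1:]
        windows = merged

    centers, mus, sigmas = [], [], []
    for lo, hi in windows:
        mask = (peak_idx >= lo) & (peak_idx < hi)
        vals = peak_int[mask]
        if vals.size == 0:
            continue
        mu = float(np.median(vals))
        sigma = 1.4826 * float(np.median(np.abs(vals - mu)))
        centers.append(float(rep.mz[(lo + hi - 1) // 2]))
        mus.append(mu)
        sigmas.append(sigma)
    if not centers:
        # no maxima at all: zero threshold everywhere
        return ThresholdCurve(np.array([rep.mz[n // 2]]), np.zeros(1), np.zeros(1),
                              np.zeros(n))
    centers_a = np.asarray(centers)
    mus_a = np.asarray(mus)
    sigmas_a = np.asarray(sigmas)
    curve = np.interp(rep.mz, centers_a, mus_a + 2.0 * sigmas_a)
    return ThresholdCurve(centers_a, mus_a, sigmas_a, curve)


def estimate_rp(rs: ReplicateSet, params: DetectionParams, tables: dict,
                models: dict, fit_params=None) -> float:
    """Estimate the effective resolution power from the data.

    The representative spectrum is split into ``n_intervals`` intervals of
    equal point counts; the most intense point of each is fitted by the
    monoisotoping procedure at every RP of the search grid, and the RP with
    the lowest mean fitting score is returned.  If even the best mean score
    is poor (no convincing isotopic structure, e.g. a noise-only spectrum)
    the value is still returned with a low-confidence warning.
    """
    from .deisotope import FitParams, best_fit_for_peak  # deferred: two-way module link

    rep = rs.representative
    if rep.size == 0 or not np.any(rep > 0):
        raise ValueError("cannot estimate resolution power on an empty spectrum")
    if fit_params is None:
        fit_params = FitParams()
    bounds = np.linspace(0, rep.size, params.n_intervals + 1).astype(int)
    anchor_peaks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        k = lo + int(np.argmax(rep[lo:hi]))
        anchor_peaks.append(Peak(float(rs.grid[k]), float(rep[k]), k))

    grid_rps = params.rp_grid()
    mean_scores = np.full(grid_rps.size, np.inf)
    for i, rp in enumerate(grid_rps):
        scores = []
        for peak in anchor_peaks:
            fit = best_fit_for_peak(peak, rs.representative, rs.grid, rp, params,
                                    fit_params, tables, models, full_stencil=True)
            if fit is not None:
                scores.append(fit.score)
        if scores:
            mean_scores[i] = float(np.mean(scores))
    best = int(np.argmin(mean_scores))
    if not np.isfinite(mean_scores[best]) or mean_scores[best] > fit_params.score_threshold:
        warnings.warn("resolution-power estimate is low-confidence: no interval "
                      "maximum produced a convincing isotopic fit", stacklevel=2)
    if not np.isfinite(mean_scores[best]):
        return float(params.rp_in)
    return float(grid_rps[best])
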