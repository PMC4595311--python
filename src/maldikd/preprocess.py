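"""Per-spectrum preprocessing: smoothing, baseline correction, normalization
and peak detection.

The stages mirror common MALDI practice: a sliding-window smoother tames
detector jitter; baseline correction removes the chemical-noise offset
(largest at low m/z, decaying towards high masses); normalization makes
intensities comparable across spectra; peak detection reduces each profile
spectrum to a sparse list of (m/z, intensity, SNR) peaks.

Default parameters follow widespread MALDIquant / MassSpecWavelet practice
and are all overridable through :class:`PreprocessConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .exceptions import (
    DegenerateSpectrumError,
    EmptySpectrumError,
    ParameterError,
)
from .spectra_io import Dataset, Spectrum

logger = logging.getLogger(__name__)

#: MAD-to-sigma consistency factor for Gaussian noise
_MAD_SCALE = 1.4826


@dataclass
class PeakList:
    """Detected peaks of one spectrum: m/z (strictly increasing), intensity,
    and optionally the SNR at each peak."""

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.snr is not None:
            self.snr = np.asarray(self.snr, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise ParameterError("mz/intensity length mismatch in peak list")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ParameterError(f"peak list {self.spectrum_id!r}: mz not strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class PreprocessConfig:
    """All tunable knobs of the per-spectrum preprocessing chain.

    ``smoothing_half_window`` etc. are in grid points; a window spans
    ``2 * half_window + 1`` points.
    """

    smoothing: str = "savitzky_golay"  # none | moving_average | savitzky_golay
    smoothing_half_window: int = 5
    poly_order: int = 3

    baseline: str = "tophat"  # none | tophat | snip | convex_hull | median
    baseline_half_window: int = 75
    snip_iterations: int = 100

    normalization: str = "tic"  # none | tic | pqn | median
    scale01: bool = True

    detection: str = "snr"  # snr | cwt
    snr_threshold: float = 8.0
    peak_half_window: int = 10
    noise_half_window: int = 100
    cwt_scales: tuple = tuple(range(1, 65))
    cwt_min_ridge_length: int = 10
    cwt_snr: float = 3.0

    def __post_init__(self) -> None:
        if self.smoothing == "savitzky_golay" and not (
            2 <= self.poly_order < 2 * self.smoothing_half_window + 1
        ):
            raise ParameterError("Savitzky-Golay order must satisfy 2 <= order < window size")
        if self.snr_threshold <= 0:
            raise ParameterError("snr_threshold must be > 0")


# --------------------------------------------------------------------------
# Smoothing


def smooth(
    s: Spectrum,
    method: str = "savitzky_golay",
    half_window: int = 5,
    poly_order: int = 3,
) -> Spectrum:
    """Smooth a spectrum with a moving average or Savitzky-Golay filter.

    The m/z grid is preserved exactly.  The moving average uses an
    unweighted window of ``2*half_window + 1`` points, shrunk at the edges;
    Savitzky-Golay fits a local least-squares polynomial of ``poly_order``
    over the same window (scipy implementation, polynomial edge handling).
    """
    if method == "none":
        return s
    if half_window < 1:
        raise ParameterError("half_window must be >= 1")
    window = 2 * half_window + 1
    if len(s) <= 2 * half_window:
        raise ParameterError(
            f"spectrum {s.id!r} too short ({len(s)}) for half_window {half_window}"
        )
    y = s.intensity
    if method == "moving_average":
        kernel = np.ones(window)
        sums = np.convolve(y, kernel, mode="same")
        counts = np.convolve(np.ones_like(y), kernel, mode="same")
        out = sums / counts
    elif method == "savitzky_golay":
        if not 2 <= poly_order < window:
            raise ParameterError("poly_order must satisfy 2 <= order < window size")
        out = signal.savgol_filter(y, window_length=window, polyorder=poly_order)
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    return s.replace_intensity(out)


# --------------------------------------------------------------------------
# Baseline correction


def _snip_baseline(y: np.ndarray, iterations: int) -> np.ndarray:
    # LLS compression stabilizes the clipping against large dynamic range
    z = np.log(np.log(np.sqrt(np.clip(y, 0, None) + 1.0) + 1.0) + 1.0)
    n = len(z)
    w_max = min(iterations, (n - 1) // 2)
    for w in range(1, w_max + 1):
        left = np.empty(n)
        right = np.empty(n)
        left[w:] = z[:-w]
        left[:w] = z[0]
        right[:-w] = z[w:]
        right[-w:] = z[-1]
        z = np.minimum(z, 0.5 * (left + right))
    inv = (np.exp(np.exp(z) - 1.0) - 1.0) ** 2 - 1.0
    return np.clip(inv, 0, None)


def _lower_convex_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Baseline = lower convex hull of the point set, linearly interpolated."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on or above segment (i1, i)
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross < 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def correct_baseline(
    s: Spectrum,
    method: str = "tophat",
    half_window: int = 75,
    iterations: int = 100,
) -> tuple[Spectrum, np.ndarray]:
    """Estimate and subtract the baseline; returns (corrected, baseline).

    Methods: ``tophat`` (morphological opening with a flat structuring
    element), ``snip`` (iterative clipping on the LLS-compressed signal),
    ``convex_hull`` (lower convex hull of the point set) and ``median``
    (moving median).  Corrected intensities are clipped at zero.
    """
    y = s.intensity
    if method == "none":
        return s, np.zeros_like(y)
    if method in ("tophat", "median") and half_window <= 0:
        raise ParameterError("half_window must be > 0")
    if method == "snip" and iterations <= 0:
        raise ParameterError("iterations must be > 0")
    if method == "tophat":
        baseline = ndimage.grey_opening(y, size=2 * half_window + 1)
    elif method == "snip":
        baseline = _snip_baseline(y, iterations)
    elif method == "convex_hull":
        baseline = _lower_convex_hull(s.mz, y)
    elif method == "median":
        baseline = ndimage.median_filter(y, size=2 * half_window + 1, mode="nearest")
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    corrected = np.clip(y - baseline, 0.0, None)
    return s.replace_intensity(corrected), baseline


# --------------------------------------------------------------------------
# Normalization


def normalize(batch: Sequence[Spectrum], method: str = "tic") -> list[Spectrum]:
    """Normalize a batch of spectra so intensities are comparable.

    ``tic`` divides each spectrum by its intensity sum (sum becomes 1);
    ``median`` by its median intensity; ``pqn`` first TIC-normalizes, builds
    the point-wise median reference over the batch (all spectra must share
    one m/z grid) and divides each spectrum by the median of its point-wise
    quotients against that reference.
    """
    if method == "none":
        return list(batch)
    batch = list(batch)
    if method == "tic":
        out = []
        for s in batch:
            total = s.intensity.sum()
            if total <= 0:
                raise DegenerateSpectrumError(f"{s.id!r}: zero total intensity")
            out.append(s.replace_intensity(s.intensity / total))
        return out
    if method == "median":
        out = []
        for s in batch:
            med = np.median(s.intensity)
            if med <= 0:
                raise DegenerateSpectrumError(f"{s.id!r}: zero median intensity")
            out.append(s.replace_intensity(s.intensity / med))
        return out
    if method == "pqn":
        if len(batch) < 2:
            raise ParameterError("PQN needs a batch of >= 2 spectra")
        grid = batch[0].mz
        for s in batch[1:]:
            if len(s.mz) != len(grid) or not np.allclose(s.mz, grid):
                raise ParameterError("PQN requires all spectra on a common m/z grid")
        tic = normalize(batch, "tic")
        stack = np.stack([s.intensity for s in tic])
        reference = np.median(stack, axis=0)
        mask = reference > 0
        if not mask.any():
            raise DegenerateSpectrumError("PQN reference spectrum is all zero")
        out = []
        for s in tic:
            quotients = s.intensity[mask] / reference[mask]
            factor = np.median(quotients)
            if factor <= 0:
                raise DegenerateSpectrumError(f"{s.id!r}: non-positive PQN quotient median")
            out.append(s.replace_intensity(s.intensity / factor))
        return out
    raise ParameterError(f"unknown normalization method {method!r}")


# --------------------------------------------------------------------------
# Peak detection


def _rolling_mad_noise(y: np.ndarray, half_window: int) -> np.ndarray:
    size = 2 * half_window + 1
    med = ndimage.median_filter(y, size=size, mode="nearest")
    mad = ndimage.median_filter(np.abs(y - med), size=size, mode="nearest")
    return _MAD_SCALE * mad


def detect_peaks(
    s: Spectrum,
    method: str = "snr",
    *,
    snr_threshold: float = 8.0,
    peak_half_window: int = 10,
    noise_half_window: int = 100,
    cwt_scales: Sequence[int] = tuple(range(1, 65)),
    cwt_min_ridge_length: int = 10,
    cwt_snr: float = 3.0,
) -> PeakList:
    """Reduce a spectrum to its peaks.

    ``snr``: a point is a peak if it is the maximum of the sliding window
    of ``2 * peak_half_window + 1`` points around it (so broad-peak flank
    wiggles are not reported as extra peaks) and its intensity is at least
    ``snr_threshold`` times the local noise, estimated as the scaled
    median absolute deviation in a window of ``2 * noise_half_window + 1``
    points.

    ``cwt``: Mexican-hat continuous wavelet transform over ``cwt_scales``
    with ridge-line linking; peaks kept when the ridge is at least
    ``cwt_min_ridge_length`` scales long and its SNR is >= ``cwt_snr``
    (scipy ``find_peaks_cwt``).  The CWT route tolerates raw spectra
    without prior smoothing or baseline correction.
    """
    if len(s) == 0:
        raise EmptySpectrumError("cannot detect peaks on an empty spectrum")
    y = s.intensity
    if method == "snr":
        if snr_threshold <= 0:
            raise ParameterError("snr_threshold must be > 0")
        if peak_half_window < 1:
            raise ParameterError("peak_half_window must be >= 1")
        if len(y) < 3:
            return PeakList(s.id, np.array([]), np.array([]), np.array([]))
        noise = _rolling_mad_noise(y, noise_half_window)
        # baseline clipping zeroes whole stretches (local MAD -> 0); floor the
        # local estimate with half the global MAD so SNR stays meaningful there
        global_mad = _MAD_SCALE * float(np.median(np.abs(y - np.median(y))))
        floor = max(0.5 * global_mad, 1e-12 * max(float(y.max()), 1.0))
        noise = np.maximum(noise, floor)
        window_max = ndimage.maximum_filter1d(y, size=2 * peak_half_window + 1)
        is_max = np.zeros(len(y), dtype=bool)
        # strict rise on the left breaks plateau ties deterministically
        is_max[1:-1] = (
            (y[1:-1] == window_max[1:-1])
            & (y[1:-1] > y[:-2])
            & (y[1:-1] >= y[2:])
            & (y[1:-1] > 0)
        )
        snr = y / noise
        keep = is_max & (snr >= snr_threshold)
        idx = np.flatnonzero(keep)
        return PeakList(s.id, s.mz[idx], y[idx], snr[idx])
    if method == "cwt":
        idx = signal.find_peaks_cwt(
            y,
            widths=np.asarray(list(cwt_scales), dtype=float),
            min_length=cwt_min_ridge_length,
            min_snr=cwt_snr,
        )
        idx = np.sort(np.asarray(idx, dtype=int))
        return PeakList(s.id, s.mz[idx], y[idx], None)
    raise ParameterError(f"unknown detection method {method!r}")


def scale_intensities(p: PeakList) -> PeakList:
    """Min-max scale peak intensities to [0, 1] (per spectrum).

    A zero-range list (single peak, or all intensities equal) maps to all
    ones — downstream presence/absence semantics treat any detected peak as
    fully present.
    """
    if len(p) == 0:
        raise ParameterError("cannot scale an empty peak list")
    lo, hi = float(p.intensity.min()), float(p.intensity.max())
    if hi == lo:
        scaled = np.ones_like(p.intensity)
    else:
        scaled = (p.intensity - lo) / (hi - lo)
    return PeakList(p.spectrum_id, p.mz.copy(), scaled, None if p.snr is None else p.snr.copy())


# --------------------------------------------------------------------------
# Chained pipeline


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig) -> PeakList:
    """Apply smoothing, baseline correction and detection to one spectrum.

    Batch-level normalization is not applied here; use
    :func:`preprocess_dataset` when TIC/PQN/median normalization is wanted.
    """
    s = smooth(s, cfg.smoothing, cfg.smoothing_half_window, cfg.poly_order)
    s, _ = correct_baseline(s, cfg.baseline, cfg.baseline_half_window, cfg.snip_iterations)
    if cfg.normalization != "none":
        s = normalize([s], cfg.normalization if cfg.normalization != "pqn" else "tic")[0]
    peaks = detect_peaks(
        s,
        cfg.detection,
        snr_threshold=cfg.snr_threshold,
        peak_half_window=cfg.peak_half_window,
        noise_half_window=cfg.noise_half_window,
        cwt_scales=cfg.cwt_scales,
        cwt_min_ridge_length=cfg.cwt_min_ridge_length,
        cwt_snr=cfg.cwt_snr,
    )
    if cfg.scale01 and len(peaks):
        peaks = scale_intensities(peaks)
    return peaks


def preprocess_dataset(
    dataset: Dataset, cfg: PreprocessConfig | None = None
) -> dict[str, list[PeakList]]:
    """Preprocess every replicate of a dataset; returns sample -> peak lists.

    Smoothing and baseline correction run per spectrum; normalization runs
    over the whole batch (PQN needs the batch); detection and optional
    [0,1] scaling run per spectrum afterwards.
    """
    cfg = cfg or PreprocessConfig()
    prepared: list[Spectrum] = []
    for s in dataset.all_spectra():
        t = smooth(s, cfg.smoothing, cfg.smoothing_half_window, cfg.poly_order)
        t, _ = correct_baseline(t, cfg.baseline, cfg.baseline_half_window, cfg.snip_iterations)
        prepared.append(t)
    prepared = normalize(prepared, cfg.normalization)
    out: dict[str, list[PeakList]] = {sid: [] for sid in dataset.samples}
    for t in prepared:
        peaks = detect_peaks(
            t,
            cfg.detection,
            snr_threshold=cfg.snr_threshold,
            noise_half_window=cfg.noise_half_window,
            cwt_scales=cfg.cwt_scales,
            cwt_min_ridge_length=cfg.cwt_min_ridge_length,
            cwt_snr=cfg.cwt_snr,
        )
        if cfg.scale01 and len(peaks):
            peaks = scale_intensities(peaks)
        out[t.sample_id].append(peaks)
    return out
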