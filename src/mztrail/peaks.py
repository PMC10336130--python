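"""Statistics-driven elution peak detection.

Detection runs once, on composite mass tracks. Per track the algorithm:

1. estimates baseline and noise level from robust statistics of the
   nonzero intensities, which decide whether the track is smoothed
   (simple moving average) and/or detrended (shifting chromatographic
   background regressed out);
2. splits the track into segments of consecutive signal above the noise
   floor, separated by gaps of sub-threshold scans;
3. searches each segment for local maxima with height and prominence
   requirements set from the segment's own statistics;
4. scores every candidate against a Gaussian model and applies the
   shape / SNR / point-count thresholds. Only peaks passing all of them
   are retained, so the default output contains no badly shaped peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import pearsonr

__all__ = [
    "TrackStats",
    "ElutionPeak",
    "PeakParams",
    "estimate_track_stats",
    "smooth_track",
    "detrend_track",
    "detect_peaks",
    "detect_peaks_on_array",
    "gaussian_shape",
]


@dataclass
class TrackStats:
    baseline: float
    noise_level: float
    needs_smoothing: bool = False
    needs_detrend: bool = False


@dataclass
class ElutionPeak:
    """One detected elution peak on a (composite) mass track."""

    row_id: int
    apex_index: int
    apex_time: float
    left_base: int   # inclusive scan indices on the track's time base
    right_base: int
    height: float    # apex intensity, baseline-subtracted
    area: float      # sum of raw in-peak intensities
    shape: float = 0.0
    snr: float = 0.0
    cselectivity: float = 1.0

    @property
    def n_points(self) -> int:
        return self.right_base - self.left_base + 1


@dataclass
class PeakParams:
    """Detection thresholds. Defaults target routine high-resolution
    Orbitrap-style data; all are configurable."""

    min_peak_height: float = 10_000.0
    min_peak_points: int = 6
    min_shape: float = 0.5
    min_snr: float = 3.0
    min_prominence_fraction: float = 0.1
    gap_scans: int = 3
    smoothing_window: int = 5
    noise_smoothing_ratio: float = 0.05
    snr_cap: float = 1000.0


def estimate_track_stats(intensities: np.ndarray) -> TrackStats:
    """Robust baseline / noise estimate from the nonzero intensities.

    Baseline is the 25th percentile of nonzero points; noise is the
    scaled median absolute deviation (x1.4826) of the points at or below
    the baseline — robust even when peaks occupy a minority of scans.
    An all-zero track yields zeros and is skipped downstream.
    """
    x = np.asarray(intensities, dtype=float)
    nz = x[x > 0]
    if nz.size == 0:
        return TrackStats(0.0, 0.0)
    baseline = float(np.percentile(nz, 25))
    band = nz[nz <= baseline]
    if band.size:
        noise = float(1.4826 * np.median(np.abs(band - np.median(band))))
    else:
        noise = 0.0
    peak_max = float(nz.max())
    needs_smoothing = peak_max > 0 and (noise / peak_max) > 0.05
    # shifting background: compare the low quantile across track thirds
    thirds = np.array_split(x, 3)
    seg_base = [np.percentile(s[s > 0], 25) if np.any(s > 0) else 0.0 for s in thirds]
    needs_detrend = (max(seg_base) - min(seg_base)) > max(3.0 * noise, 0.5 * baseline, 1.0)
    return TrackStats(baseline, noise, needs_smoothing, needs_detrend)


def smooth_track(intensities: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered simple moving average; edges padded by reflection."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(intensities, dtype=float)
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def detrend_track(intensities: np.ndarray, window: int | None = None) -> np.ndarray:
    """Regress out a shifting chromatographic background.

    The trend is a running-minimum envelope smoothed by a moving average
    of the same window; subtracting it leaves peaks in place (apexes move
    by at most a scan on ramp-plus-peak data). Output clipped at 0.
    """
    x = np.asarray(intensities, dtype=float)
    n = x.size
    if window is None:
        window = max(11, (n // 10) | 1)
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    env = np.empty(n)
    for i in range(n):
        env[i] = padded[i : i + window].min()
    trend = smooth_track(env, window)
    return np.clip(x - trend, 0.0, None)


def _gaussian(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def gaussian_shape(intensities: np.ndarray, left: int, right: int) -> float:
    """Gaussian fitness of the window [left, right] (inclusive): Pearson r
    between a least-squares Gaussian fit and the data, clipped to [0, 1].
    Non-convergence scores 0."""
    y = np.asarray(intensities[left : right + 1], dtype=float)
    t = np.arange(y.size, dtype=float)
    if y.size < 3 or y.max() <= 0:
        return 0.0
    a0 = float(y.max())
    mu0 = float(t[np.argmax(y)])
    sigma0 = max(y.size / 6.0, 1.0)
    try:
        popt, _ = curve_fit(
            _gaussian, t, y, p0=(a0, mu0, sigma0),
            bounds=([0, -y.size, 0.25], [10 * a0, 2 * y.size, 10 * y.size]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return 0.0
    fit = _gaussian(t, *popt)
    if np.std(fit) == 0 or np.std(y) == 0:
        return 0.0
    r = pearsonr(fit, y).statistic
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(r, 0.0, 1.0))


def _segments(above: np.ndarray, gap_scans: int) -> list[tuple[int, int]]:
    """Runs of True, joining runs separated by fewer than gap_scans False."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    segs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev >= gap_scans + 1:
            segs.append((start, prev))
            start = i
        prev = i
    segs.append((start, prev))
    return segs


def detect_peaks_on_array(
    intensities: np.ndarray,
    times: np.ndarray,
    stats: TrackStats | None = None,
    params: PeakParams | None = None,
    row_id: int = -1,
    resampled: bool = False,
) -> list[ElutionPeak]:
    """Full detection pipeline on a raw intensity vector. ``times`` gives
    the scan times used for apex_time; SNR and cSelectivity are computed
    against the raw (unsmoothed) track. ``resampled`` marks composites
    built through non-identity RT maps (see composite module)."""
    from . import metrics  # local import avoids a cycle

    params = params or PeakParams()
    raw = np.asarray(intensities, dtype=float)
    if stats is None:
        stats = estimate_track_stats(raw)
    if raw.max(initial=0.0) <= 0:
        return []
    x = raw
    if stats.needs_detrend:
        x = detrend_track(x)
    if stats.needs_smoothing:
        x = smooth_track(x, params.smoothing_window)
    elif resampled:
        # minimal pass to heal single-bin resampling notches
        x = smooth_track(x, 3)

    floor = max(stats.baseline, stats.noise_level)
    above = x > floor
    candidates: list[ElutionPeak] = []
    for s0, s1 in _segments(above, params.gap_scans):
        seg = x[s0 : s1 + 1]
        if seg.size < params.min_peak_points:
            continue
        seg_max = seg.max()
        prominence = max(params.min_prominence_fraction * seg_max, stats.noise_level)
        height = max(params.min_peak_height, floor)
        # pad so maxima at segment edges are still found
        padded = np.concatenate(([seg.min()], seg, [seg.min()]))
        apexes, _ = find_peaks(padded, height=height, prominence=prominence)
        apexes = apexes - 1
        if apexes.size == 0:
            continue
        # boundaries: local minima between adjacent apexes, segment edges outside
        bounds = [s0]
        for a, b in zip(apexes[:-1], apexes[1:]):
            bounds.append(s0 + a + int(np.argmin(seg[a : b + 1])))
        bounds.append(s1)
        for k, apex in enumerate(apexes):
            left = bounds[k]
            right = bounds[k + 1]
            peak = ElutionPeak(
                row_id=row_id,
                apex_index=s0 + int(apex),
                apex_time=float(times[s0 + int(apex)]),
                left_base=int(left),
                right_base=int(right),
                height=float(x[s0 + int(apex)] - stats.baseline),
                area=float(raw[left : right + 1].sum()),
            )
            if peak.n_points < params.min_peak_points:
                continue
            if peak.height < params.min_peak_height:
                continue
            peak.shape = gaussian_shape(raw, peak.left_base, peak.right_base)
            if peak.shape < params.min_shape:
                continue
            candidates.append(peak)

    # SNR excludes points inside ANY candidate peak's range
    retained = []
    for p in candidates:
        p.snr = metrics.compute_snr(raw, p, candidates, cap=params.snr_cap)
        if p.snr >= params.min_snr:
            retained.append(p)
    for p in retained:
        p.cselectivity = metrics.compute_cselectivity(raw, p, retained)
    return retained


def detect_peaks(track, stats: TrackStats | None = None,
                 params: PeakParams | None = None) -> list[ElutionPeak]:
    """Detect elution peaks on a :class:`~mztrail.composite.CompositeMassTrack`."""
    return detect_peaks_on_array(
        track.intensities, track.time_base, stats=stats, params=params,
        row_id=track.row_id, resampled=getattr(track, "resampled", False),
    )
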