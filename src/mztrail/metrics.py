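"""Feature quality metrics: SNR, cSelectivity, mSelectivity.

SNR is peak height divided by the noise level, where noise is the mean
intensity of up to 100 non-peak data points flanking each side of the
peak — every point inside any retained peak's range counts as peak, all
other track points count as noise.

cSelectivity measures how distinct a chromatographic peak is: after
filtering the track to points above half the peak's height, it is the
fraction of those points lying inside any retained peak. It is 1 when
the chromatogram has no noise above half-height.

mSelectivity measures how distinguishable an m/z value is from its
neighbors when the matching error is modeled as a Gaussian with scale
set by the ppm mass resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mass_tracks import ppm_halfwidth

__all__ = [
    "MSelectivityProfile",
    "compute_snr",
    "compute_cselectivity",
    "compute_mselectivity",
]


def _peak_mask(n: int, peaks) -> np.ndarray:
    """Boolean mask of scans inside any peak's [left, right] (inclusive)."""
    mask = np.zeros(n, dtype=bool)
    for p in peaks:
        mask[p.left_base : p.right_base + 1] = True
    return mask


def compute_snr(intensities: np.ndarray, peak, all_peaks, *,
                n_flank: int = 100, noise_floor: float = 1.0,
                cap: float = 1000.0) -> float:
    """Signal-to-noise ratio of ``peak`` on its track.

    Noise = mean of up to ``n_flank`` non-peak points on each side of the
    peak (nearest first); points inside ANY retained peak are excluded.
    A noise-free flank would divide by zero, so noise is floored at
    ``noise_floor`` and the ratio capped at ``cap`` to stay finite and
    sortable on clean synthetic tracks.
    """
    x = np.asarray(intensities, dtype=float)
    mask = _peak_mask(x.size, all_peaks)
    left_idx = [i for i in range(peak.left_base - 1, -1, -1) if not mask[i]][:n_flank]
    right_idx = [i for i in range(peak.right_base + 1, x.size) if not mask[i]][:n_flank]
    flank = left_idx + right_idx
    noise = float(np.mean(x[flank])) if flank else 0.0
    snr = peak.height / max(noise, noise_floor)
    return float(min(snr, cap))


def compute_cselectivity(intensities: np.ndarray, peak, all_peaks) -> float:
    """Fraction of track points above half the peak's apex height that lie
    inside any retained peak's boundaries (inclusive). The apex itself
    qualifies, so the denominator is never zero."""
    x = np.asarray(intensities, dtype=float)
    half = x[peak.apex_index] / 2.0
    qualifying = x > half
    total = int(qualifying.sum())
    if total == 0:  # defensive; apex qualifies unless track is all-zero
        return 1.0
    inside = int((qualifying & _peak_mask(x.size, all_peaks)).sum())
    return inside / total


@dataclass
class MSelectivityProfile:
    mz_list: np.ndarray
    ppm: float
    scores: np.ndarray


def compute_mselectivity(mz_list, ppm: float = 5.0) -> MSelectivityProfile:
    """m/z selectivity under a Gaussian error model.

    With per-feature scale sigma_i = ppm * mz_i * 1e-6, the score is

        score_i = max(0, 1 - sum_{j != i} exp(-(mz_j - mz_i)^2 / (2 sigma_i^2)))

    An isolated m/z scores 1; an exact duplicate scores 0; a pair at
    2 sigma scores 1 - e^-2. Neighbors beyond 10 sigma contribute less
    than 1e-21 and are skipped.
    """
    mz = np.asarray(mz_list, dtype=float)
    if mz.ndim != 1:
        raise ValueError("mz_list must be one-dimensional")
    if np.any(np.diff(mz) < 0):
        raise ValueError("mz_list must be sorted ascending")
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    scores = np.ones(mz.size)
    for i, m in enumerate(mz):
        sigma = ppm_halfwidth(m, ppm)
        lo = np.searchsorted(mz, m - 10 * sigma)
        hi = np.searchsorted(mz, m + 10 * sigma, side="right")
        neigh = np.r_[mz[lo:i], mz[i + 1 : hi]]
        if neigh.size:
            contrib = np.exp(-((neigh - m) ** 2) / (2.0 * sigma**2)).sum()
            scores[i] = max(0.0, 1.0 - contrib)
    return MSelectivityProfile(mz_list=mz, ppm=ppm, scores=scores)
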