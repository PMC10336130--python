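"""Composite mass tracks: the cross-sample substrate of peak detection.

Each MassGrid row's member tracks are remapped onto the reference time
base (nearest reference scan — a permutation of points into bins, which
conserves every member's total intensity exactly) and summed. The
composite track has higher signal than any single sample, so weak but
recurrent peaks become detectable, and a peak present in only one sample
still rises above the composite baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mass_grid import MassGrid
from .rt_align import RTMap

__all__ = ["CompositeMassTrack", "build_composite_track", "build_composites",
           "scan_index_map"]


@dataclass
class CompositeMassTrack:
    row_id: int
    grid_mz: float
    time_base: np.ndarray = field(repr=False)
    intensities: np.ndarray = field(repr=False)
    #: True when members were remapped through non-identity RT maps;
    #: resampling can notch single bins (one sample skips a bin where its
    #: drift crosses a scan boundary), so detection lightly smooths first
    resampled: bool = False


def scan_index_map(rt_map: RTMap, sample_times: np.ndarray,
                   time_base: np.ndarray) -> np.ndarray:
    """For each sample scan, the index of the nearest reference scan after
    forward-mapping its time, made strictly increasing.

    Strict monotonicity keeps the assignment a near-bijection (scan rates
    match across samples), so no reference bin receives two scans while a
    neighbor receives none — collisions would carve spurious valleys into
    the composite. Totals are conserved exactly either way."""
    mapped = rt_map.forward(np.asarray(sample_times, dtype=float))
    idx = np.searchsorted(time_base, mapped)
    idx = np.clip(idx, 1, len(time_base) - 1)
    left = time_base[idx - 1]
    right = time_base[idx]
    idx = np.where(np.abs(mapped - left) <= np.abs(right - mapped), idx - 1, idx)
    n = len(idx)
    arange = np.arange(n)
    idx = np.maximum.accumulate(idx - arange) + arange  # strictly increasing
    return np.clip(idx, 0, len(time_base) - 1)


def build_composite_track(
    row_id: int,
    grid_mz: float,
    member_tracks,
    index_maps,
    time_base: np.ndarray,
    resampled: bool = False,
) -> CompositeMassTrack:
    """Sum member tracks onto the reference time base.

    ``member_tracks`` is one entry per sample (a MassTrack or None for a
    missing member); ``index_maps`` the per-sample nearest-reference-scan
    assignment from :func:`scan_index_map`. Missing members contribute 0.
    """
    total = np.zeros(len(time_base))
    for track, idx_map in zip(member_tracks, index_maps):
        if track is None:
            continue
        np.add.at(total, idx_map, track.intensities)
    return CompositeMassTrack(row_id, grid_mz, time_base, total, resampled=resampled)


def build_composites(
    grid: MassGrid,
    per_sample_tracks,
    rt_maps: list[RTMap],
    scan_times,
    reference_sample: int = 0,
) -> list[CompositeMassTrack]:
    """Build all composite tracks of an experiment. The reference time
    base is the reference sample's scan times."""
    time_base = np.asarray(scan_times[reference_sample], dtype=float)
    index_maps = [
        scan_index_map(rt_maps[s], np.asarray(scan_times[s], dtype=float), time_base)
        for s in range(len(per_sample_tracks))
    ]
    resampled = any(not m.is_identity for m in rt_maps) and len(per_sample_tracks) > 1
    out = []
    for r in range(grid.n_rows):
        members = [
            per_sample_tracks[s][grid.members[r, s]] if grid.members[r, s] >= 0 else None
            for s in range(len(per_sample_tracks))
        ]
        out.append(build_composite_track(r, float(grid.grid_mz[r]), members,
                                         index_maps, time_base, resampled=resampled))
    return out
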