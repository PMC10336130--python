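"""Mass track construction.

A mass track is an extracted-ion chromatogram that spans the full
retention time of a run: a zero-filled intensity vector over all scans,
carrying a single consensus m/z. Tracks are the per-sample unit on which
all later correspondence operates; within one sample, no two track
consensus m/z values lie within the ppm tolerance of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_mzml import SampleRun

__all__ = ["MassTrack", "build_mass_tracks", "ppm_halfwidth", "dump_tracks_tsv"]


def ppm_halfwidth(mz: float, ppm: float) -> float:
    """Half-width of the ppm mass-tolerance window at ``mz``, in Th.

    At 5 ppm this is 0.00075 Th for a 150 Da ion and 0.0040 Th at 800 Da —
    the scale modern high-resolution instruments resolve, and far below
    the nominal-mass bins of older software.
    """
    return mz * ppm * 1e-6


@dataclass
class MassTrack:
    """Full-RT, zero-filled chromatogram with one consensus m/z."""

    track_id: int
    mz: float
    intensities: np.ndarray = field(repr=False)
    sample_id: str = ""

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.intensities))

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())


def _gap_groups(mz_sorted: np.ndarray, ppm: float) -> list[slice]:
    """Cut a sorted m/z array into groups wherever the gap between
    neighbors exceeds the ppm tolerance (evaluated at the heavier member)."""
    if mz_sorted.size == 0:
        return []
    gaps = np.diff(mz_sorted)
    cut = gaps > ppm_halfwidth(mz_sorted[1:], ppm)
    bounds = np.flatnonzero(cut) + 1
    edges = np.concatenate(([0], bounds, [mz_sorted.size]))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _resolve_group(scan_idx, mz, inten, consensus_hint=None):
    """One centroid per scan: keep the more intense; ties go to the
    centroid closer to the running consensus. Returns (kept, leftover)
    index arrays into the group."""
    order = np.argsort(scan_idx, kind="stable")
    kept, leftover = [], []
    best_for_scan: dict[int, int] = {}
    consensus = consensus_hint
    if consensus is None:
        consensus = float(np.average(mz, weights=inten)) if inten.sum() > 0 else float(mz.mean())
    for i in order:
        s = int(scan_idx[i])
        if s not in best_for_scan:
            best_for_scan[s] = i
            continue
        j = best_for_scan[s]
        if inten[i] > inten[j] or (
            inten[i] == inten[j] and abs(mz[i] - consensus) < abs(mz[j] - consensus)
        ):
            best_for_scan[s] = i
            leftover.append(j)
        else:
            leftover.append(i)
    kept = sorted(best_for_scan.values())
    return np.asarray(kept, dtype=int), np.asarray(sorted(leftover), dtype=int)


def build_mass_tracks(
    run: SampleRun, ppm: float = 5.0, min_track_points: int = 6
) -> list[MassTrack]:
    """Group all centroids of a run into mass tracks.

    All centroids are pooled, sorted by m/z, and cut into groups wherever
    the gap between adjacent centroids exceeds the ppm tolerance. Each
    group becomes one track; its consensus m/z is the intensity-weighted
    mean of its members. If two centroids of a group fall in the same
    scan, the more intense one is kept and the displaced centroids may
    seed a separate track only if they form their own ppm-coherent group
    that does not collide with an existing consensus. Tracks with fewer
    than ``min_track_points`` nonzero scans are discarded; the result is
    sorted by m/z ascending, mutually ppm-separated.
    """
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    n_scans = run.n_scans
    scan_idx = np.concatenate(
        [np.full(m.size, i, dtype=int) for i, (m, _) in enumerate(run.scans)]
    ) if run.scans else np.empty(0, dtype=int)
    all_mz = np.concatenate([m for m, _ in run.scans]) if run.scans else np.empty(0)
    all_int = np.concatenate([x for _, x in run.scans]) if run.scans else np.empty(0)
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, scan_idx = all_mz[order], all_int[order], scan_idx[order]

    raw_tracks: list[tuple[float, np.ndarray]] = []  # (consensus mz, intensity vector)

    def _consensus(sel: np.ndarray) -> float:
        mzs, ints = all_mz[sel], all_int[sel]
        w = ints.sum()
        return float(np.average(mzs, weights=ints)) if w > 0 else float(mzs.mean())

    def _emit(sel: np.ndarray, consensus: float) -> None:
        vec = np.zeros(n_scans)
        vec[scan_idx[sel]] = all_int[sel]
        raw_tracks.append((consensus, vec))

    pending = [np.arange(a.start, a.stop) for a in _gap_groups(all_mz, ppm)]
    while pending:
        sel = pending.pop()
        scans = scan_idx[sel]
        if np.unique(scans).size == scans.size:
            _emit(sel, _consensus(sel))
            continue
        kept, leftover = _resolve_group(scans, all_mz[sel], all_int[sel])
        # consensus over ALL group members: displaced centroids measured
        # the same species, so they still inform the m/z estimate
        _emit(sel[kept], _consensus(sel))
        # displaced centroids may seed their own tracks if ppm-coherent
        lo_sel = sel[leftover]
        for g in _gap_groups(all_mz[lo_sel], ppm):
            sub = lo_sel[g]
            if np.unique(scan_idx[sub]).size == scan_idx[sub].size:
                _emit(sub, _consensus(sub))
            else:
                pending.append(sub)

    raw_tracks.sort(key=lambda t: t[0])
    # enforce per-sample uniqueness: drop the weaker of any consensus pair
    # closer than ppm (possible only via same-scan displacement)
    tracks: list[tuple[float, np.ndarray]] = []
    for mz, vec in raw_tracks:
        if tracks and mz - tracks[-1][0] <= ppm_halfwidth(mz, ppm):
            if vec.sum() > tracks[-1][1].sum():
                tracks[-1] = (mz, vec)
        else:
            tracks.append((mz, vec))

    out = [
        MassTrack(track_id=i, mz=mz, intensities=vec, sample_id=run.sample_id)
        for i, (mz, vec) in enumerate(tracks)
        if np.count_nonzero(vec) >= min_track_points
    ]
    for i, t in enumerate(out):
        t.track_id = i
    return out


def dump_tracks_tsv(tracks: list[MassTrack], path) -> None:
    """Debug dump of (track_id, mz, n_nonzero)."""
    with open(path, "w") as fh:
        fh.write("track_id\tmz\tn_nonzero\n")
        for t in tracks:
            fh.write(f"{t.track_id}\t{t.mz:.6f}\t{t.n_nonzero}\n")
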