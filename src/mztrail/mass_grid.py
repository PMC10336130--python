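"""Cross-sample m/z alignment into the MassGrid.

m/z alignment happens BEFORE elution peak detection: each sample's mass
tracks are matched to experiment-level grid rows by reciprocal nearest
neighbor within the ppm tolerance, guided by isotopic (13C/12C) and
adduct (Na/H) landmark pairs, which are matched first. A sample whose
compound is below detection limit simply leaves a hole in the row — the
row itself survives, keeping the feature alignable everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mass_tracks import MassTrack, ppm_halfwidth

__all__ = [
    "DELTA_C13",
    "DELTA_NAH",
    "AnchorPair",
    "MassGrid",
    "find_anchor_pairs",
    "align_mass_grid",
]

DELTA_C13 = 1.003355   # 13C - 12C mass difference, Th (z=1)
DELTA_NAH = 21.981944  # Na - H mass difference, Th (z=1)


@dataclass
class AnchorPair:
    """A high-confidence landmark: two tracks separated by an isotope or
    adduct mass difference."""

    track_low: int
    track_high: int
    kind: str  # "C13" or "NaH"


@dataclass
class MassGrid:
    """Experiment-level alignment of mass tracks.

    ``members[r, s]`` is the track_id of sample ``s`` in row ``r``, or -1
    where the sample has no matching track.
    """

    sample_ids: list[str]
    grid_mz: np.ndarray
    members: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return len(self.grid_mz)

    def row_members(self, row: int) -> dict[str, int]:
        return {
            s: int(t)
            for s, t in zip(self.sample_ids, self.members[row])
            if t >= 0
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("row\tgrid_mz\t" + "\t".join(self.sample_ids) + "\n")
            for r in range(self.n_rows):
                cells = ["NA" if t < 0 else str(int(t)) for t in self.members[r]]
                fh.write(f"{r}\t{self.grid_mz[r]:.6f}\t" + "\t".join(cells) + "\n")


def find_anchor_pairs(tracks: list[MassTrack], ppm: float = 5.0) -> list[AnchorPair]:
    """Find all (low, high) track pairs separated by the 13C/12C or Na/H
    mass difference within ppm tolerance (applied on the heavier member).

    ``tracks`` must be one sample's tracks sorted by m/z. A track may
    participate in multiple pairs.
    """
    mz = np.array([t.mz for t in tracks])
    if np.any(np.diff(mz) < 0):
        raise ValueError("tracks must be sorted by m/z")
    pairs: list[AnchorPair] = []
    for kind, delta in (("C13", DELTA_C13), ("NaH", DELTA_NAH)):
        for i, m in enumerate(mz):
            target = m + delta
            tol = ppm_halfwidth(target, ppm)
            lo = np.searchsorted(mz, target - tol)
            hi = np.searchsorted(mz, target + tol, side="right")
            for j in range(lo, hi):
                pairs.append(AnchorPair(tracks[i].track_id, tracks[j].track_id, kind))
    return pairs


class _GridBuilder:
    """Mutable grid rows during alignment; one entry per row."""

    def __init__(self, n_samples: int):
        self.mz: list[float] = []       # running weighted consensus
        self.weight: list[float] = []   # running weight (intensity + 1 per member)
        self.members: list[dict[int, int]] = []  # sample slot -> track_id
        self.n_samples = n_samples

    def add_row(self, mz: float, weight: float, slot: int, track_id: int) -> int:
        self.mz.append(mz)
        self.weight.append(weight)
        self.members.append({slot: track_id})
        return len(self.mz) - 1

    def join(self, row: int, mz: float, weight: float, slot: int, track_id: int) -> None:
        w0, w1 = self.weight[row], weight
        self.mz[row] = (self.mz[row] * w0 + mz * w1) / (w0 + w1)
        self.weight[row] += w1
        self.members[row][slot] = track_id


def _reciprocal_matches(grid_mz: np.ndarray, track_mz: np.ndarray, ppm: float):
    """Reciprocal-nearest-neighbor pairs (row_idx, track_idx) within ppm."""
    if grid_mz.size == 0 or track_mz.size == 0:
        return []
    order = np.argsort(grid_mz, kind="stable")
    gm = grid_mz[order]

    def nearest_row(m):
        k = np.searchsorted(gm, m)
        cands = [c for c in (k - 1, k) if 0 <= c < gm.size]
        best = min(cands, key=lambda c: abs(gm[c] - m))
        return order[best] if abs(gm[best] - m) <= ppm_halfwidth(m, ppm) else -1

    t_order = np.argsort(track_mz, kind="stable")
    tm = track_mz[t_order]

    def nearest_track(m):
        k = np.searchsorted(tm, m)
        cands = [c for c in (k - 1, k) if 0 <= c < tm.size]
        best = min(cands, key=lambda c: abs(tm[c] - m))
        return t_order[best] if abs(tm[best] - m) <= ppm_halfwidth(m, ppm) else -1

    matches = []
    for ti, m in enumerate(track_mz):
        r = nearest_row(m)
        if r >= 0 and nearest_track(grid_mz[r]) == ti:
            matches.append((int(r), ti))
    return matches


def align_mass_grid(per_sample_tracks: list[list[MassTrack]], ppm: float = 5.0) -> MassGrid:
    """Align per-sample mass tracks into a MassGrid.

    The grid is seeded from the sample with the most tracks; remaining
    samples are folded in by reciprocal nearest neighbor within the ppm
    tolerance. Tracks participating in isotope/adduct anchor pairs are
    matched first (landmarks constrain the mapping), unmatched tracks
    open new rows, and each row's consensus m/z is the intensity-weighted
    running mean, finalized by a full recompute. Rows whose consensus m/z
    values end up closer than the tolerance are merged, so the final grid
    obeys the mass resolution. The result is independent of sample input
    order.
    """
    if not per_sample_tracks:
        raise ValueError("need at least one sample")
    sample_ids = [
        (ts[0].sample_id if ts else f"sample{i}") for i, ts in enumerate(per_sample_tracks)
    ]
    # canonical processing order: most tracks first, sample_id as tie-break
    proc = sorted(
        range(len(per_sample_tracks)),
        key=lambda i: (-len(per_sample_tracks[i]), sample_ids[i]),
    )
    builder = _GridBuilder(len(per_sample_tracks))

    for slot in proc:
        tracks = per_sample_tracks[slot]
        if not tracks:
            continue
        track_mz = np.array([t.mz for t in tracks])
        weights = np.array([t.total_intensity + 1.0 for t in tracks])
        grid_mz = np.asarray(builder.mz)
        matched_rows: set[int] = set()
        matched_tracks: set[int] = set()
        pairs = _reciprocal_matches(grid_mz, track_mz, ppm)
        # landmark tracks first: they are high-confidence guides
        anchored = set()
        for ap in find_anchor_pairs(tracks, ppm):
            anchored.add(ap.track_low)
            anchored.add(ap.track_high)
        id_to_idx = {t.track_id: i for i, t in enumerate(tracks)}
        anchored_idx = {id_to_idx[a] for a in anchored}
        for prio in (True, False):
            for r, ti in pairs:
                if (ti in anchored_idx) != prio:
                    continue
                if r in matched_rows or ti in matched_tracks:
                    continue
                builder.join(r, track_mz[ti], weights[ti], slot, tracks[ti].track_id)
                matched_rows.add(r)
                matched_tracks.add(ti)
        for ti in range(len(tracks)):
            if ti not in matched_tracks:
                builder.add_row(track_mz[ti], weights[ti], slot, tracks[ti].track_id)

    # final consensus recompute + merge of rows violating the separation rule
    rows = sorted(
        zip(builder.mz, builder.weight, builder.members), key=lambda r: r[0]
    )
    merged: list[list] = []
    for mz, w, mem in rows:
        if merged and mz - merged[-1][0] <= ppm_halfwidth(mz, ppm):
            pmz, pw, pmem = merged[-1]
            new_mem = dict(pmem)
            for slot, tid in mem.items():
                if slot in new_mem:
                    # conflict: keep the member closer to the merged consensus
                    cur = per_sample_tracks[slot][new_mem[slot]].mz
                    cand = per_sample_tracks[slot][tid].mz
                    cons = (pmz * pw + mz * w) / (pw + w)
                    if abs(cand - cons) < abs(cur - cons):
                        new_mem[slot] = tid
                else:
                    new_mem[slot] = tid
            merged[-1] = [(pmz * pw + mz * w) / (pw + w), pw + w, new_mem]
        else:
            merged.append([mz, w, mem])

    n_samples = len(per_sample_tracks)
    grid_mz = np.empty(len(merged))
    members = np.full((len(merged), n_samples), -1, dtype=int)
    for r, (mz, _, mem) in enumerate(merged):
        num = den = 0.0
        for slot, tid in mem.items():
            t = per_sample_tracks[slot][tid]
            w = t.total_intensity + 1.0
            num += t.mz * w
            den += w
            members[r, slot] = tid
        grid_mz[r] = num / den if den else mz
    order = np.argsort(grid_mz, kind="stable")
    return MassGrid(sample_ids=sample_ids, grid_mz=grid_mz[order], members=members[order])
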