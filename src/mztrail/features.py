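"""Feature table construction and per-sample quantification.

A feature is an experiment-level (m/z, RT) pair: one composite-track
elution peak tied to its MassGrid row. Quantification inverse-maps the
peak boundaries onto each sample's own time base and sums that sample's
track intensities over the window — so per-sample values come straight
from per-sample data, and RT-regression error cannot bias them. Samples
whose track is missing (or empty in the window) get area 0 with the
detected flag down: absence is biology to be reported, not a gap to
silently drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .composite import CompositeMassTrack
from .mass_grid import DELTA_C13, DELTA_NAH, MassGrid
from .mass_tracks import ppm_halfwidth
from .metrics import compute_mselectivity
from .peaks import ElutionPeak
from .rt_align import RTMap

__all__ = ["Feature", "FeatureTable", "quantify", "export_table",
           "group_empirical_compounds"]


@dataclass
class Feature:
    feature_id: str
    row_id: int
    mz: float
    rt_apex: float
    rt_left: float
    rt_right: float
    shape: float
    snr: float
    cselectivity: float
    mselectivity: float = 1.0
    areas: dict[str, float] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)


@dataclass
class FeatureTable:
    sample_ids: list[str]
    features: list[Feature]

    def __len__(self) -> int:
        return len(self.features)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            row = {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "rt_apex": f.rt_apex,
                "rt_left": f.rt_left,
                "rt_right": f.rt_right,
                "shape": f.shape,
                "snr": f.snr,
                "cselectivity": f.cselectivity,
                "mselectivity": f.mselectivity,
            }
            for s in self.sample_ids:
                row[s] = f.areas.get(s, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def quantify(
    composite_peaks: list[tuple[CompositeMassTrack, ElutionPeak]],
    grid: MassGrid,
    per_sample_tracks,
    rt_maps: list[RTMap],
    scan_times,
    ppm: float = 5.0,
    detected_height_fraction: float = 0.1,
) -> FeatureTable:
    """Build the feature table from composite-track peaks.

    For each (composite track, peak) and each sample, the peak's boundary
    times are inverse-mapped to the sample's time base; the sample's area
    is the sum of its own track intensities over that window. The
    detected flag requires area > 0 and a window maximum of at least
    ``detected_height_fraction`` x (composite apex height / n_samples).
    mSelectivity is computed over the final feature m/z list at ``ppm``.
    """
    sample_ids = grid.sample_ids
    n_samples = len(sample_ids)
    feats: list[Feature] = []
    ordered = sorted(
        composite_peaks, key=lambda cp: (cp[0].grid_mz, cp[1].apex_time)
    )
    for k, (ctrack, peak) in enumerate(ordered):
        t_left = float(ctrack.time_base[peak.left_base])
        t_right = float(ctrack.time_base[peak.right_base])
        f = Feature(
            feature_id=f"F{k + 1}",
            row_id=ctrack.row_id,
            mz=ctrack.grid_mz,
            rt_apex=peak.apex_time,
            rt_left=t_left,
            rt_right=t_right,
            shape=peak.shape,
            snr=peak.snr,
            cselectivity=peak.cselectivity,
        )
        for s in range(n_samples):
            sid = sample_ids[s]
            tid = grid.members[ctrack.row_id, s]
            if tid < 0:
                f.areas[sid] = 0.0
                f.detected[sid] = False
                continue
            track = per_sample_tracks[s][tid]
            times = np.asarray(scan_times[s], dtype=float)
            lo = rt_maps[s].inverse(t_left)
            hi = rt_maps[s].inverse(t_right)
            i0 = int(np.searchsorted(times, lo - 1e-9))
            i1 = int(np.searchsorted(times, hi + 1e-9, side="right")) - 1
            window = track.intensities[i0 : i1 + 1]
            area = float(window.sum())
            f.areas[sid] = area
            wmax = float(window.max()) if window.size else 0.0
            f.detected[sid] = (
                area > 0
                and wmax >= detected_height_fraction * peak.height / max(n_samples, 1)
            )
        feats.append(f)
    if feats:
        order = np.argsort([f.mz for f in feats], kind="stable")
        msel = compute_mselectivity([feats[i].mz for i in order], ppm=ppm)
        for rank, i in enumerate(order):
            feats[i].mselectivity = float(msel.scores[rank])
    return FeatureTable(sample_ids=list(sample_ids), features=feats)


def export_table(table: FeatureTable, path) -> None:
    """Write the feature table as TSV: metric columns first, then one area
    column per sample in stable sample order. Identical inputs produce
    byte-identical files."""
    if not table.features:
        raise ValueError("feature table is empty")
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def group_empirical_compounds(
    table: FeatureTable, ppm: float = 5.0, rt_tolerance_s: float = 6.0
) -> dict[str, list[str]]:
    """Group degenerate features into empirical compounds.

    Two features link when their m/z difference matches the 13C/12C or
    Na/H spacing within ppm (tolerance on the heavier member) AND their
    apex RTs agree within ``rt_tolerance_s``. Connected components are
    the groups; singletons stay their own group.
    """
    g = nx.Graph()
    feats = sorted(table.features, key=lambda f: f.mz)
    for f in feats:
        g.add_node(f.feature_id)
    mz = np.array([f.mz for f in feats])
    for i, f in enumerate(feats):
        for delta in (DELTA_C13, DELTA_NAH):
            target = f.mz + delta
            tol = ppm_halfwidth(target, ppm)
            lo = np.searchsorted(mz, target - tol)
            hi = np.searchsorted(mz, target + tol, side="right")
            for j in range(lo, hi):
                if abs(feats[j].rt_apex - f.rt_apex) <= rt_tolerance_s:
                    g.add_edge(f.feature_id, feats[j].feature_id)
    groups = {}
    for k, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: min(c))
    ):
        groups[f"EC{k + 1}"] = sorted(comp)
    return groups


def export_empirical_compounds(groups: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        json.dump(groups, fh, indent=1, sort_keys=True)
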