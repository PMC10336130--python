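"""Retention-time alignment by LOWESS regression.

A small set of high-quality reference peaks — rows present in every
sample whose track carries exactly one clean elution peak — calibrates a
per-sample LOWESS curve of sample time against reference time. The fit
is monotonized by isotonic projection and exposed as a bidirectional
remapping: `forward` sends a sample time onto the reference (composite)
time base, `inverse` sends composite times back to the sample. Because
quantification uses only inverse-mapped boundaries, regression error
affects peak ranges on the composite but never the per-sample readout.
RT alignment never touches the MassGrid: m/z assignment is immutable
through this stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .mass_grid import MassGrid
from .peaks import PeakParams, detect_peaks_on_array

__all__ = ["RTMap", "select_reference_peaks", "fit_rt_map", "fit_experiment_rt_maps"]

#: stringent thresholds for the quick per-sample detection pass that
#: selects alignment references
REFERENCE_PEAK_PARAMS = PeakParams(min_shape=0.8, min_snr=10.0)


@dataclass
class RTMap:
    """Monotone bidirectional time remapping for one sample.

    ``sample_nodes`` / ``reference_nodes`` are matched monotone arrays;
    between nodes the map interpolates linearly, outside them it
    extrapolates with the boundary offset held constant.
    """

    sample_id: str
    sample_nodes: np.ndarray = field(repr=False)
    reference_nodes: np.ndarray = field(repr=False)

    @classmethod
    def identity(cls, sample_id: str = "") -> "RTMap":
        nodes = np.array([0.0, 1.0])
        return cls(sample_id, nodes, nodes.copy())

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.sample_nodes, self.reference_nodes)

    def _map(self, t, xp: np.ndarray, fp: np.ndarray):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, xp, fp)
        out = np.where(t < xp[0], t + (fp[0] - xp[0]), out)
        out = np.where(t > xp[-1], t + (fp[-1] - xp[-1]), out)
        return float(out) if out.ndim == 0 else out

    def forward(self, t):
        """Sample time -> reference (composite) time."""
        return self._map(t, self.sample_nodes, self.reference_nodes)

    def inverse(self, t):
        """Reference (composite) time -> sample time."""
        return self._map(t, self.reference_nodes, self.sample_nodes)


def fit_rt_map(ref_pairs, frac: float | None = None, sample_id: str = "") -> RTMap:
    """Fit a LOWESS RT map from (reference time, sample time) pairs.

    LOWESS (span ``frac``, 2 robustifying iterations) regresses sample
    time on reference time; the fitted values are projected onto the
    monotone cone (isotonic regression) since a time map that runs
    backwards is physically meaningless. The default span is adaptive:
    each local window covers at least ~8 reference pairs but never less
    than 30% of the range — wide windows over curved drifts incur
    boundary bias, narrow ones chase individual references. Degenerate
    input (fewer than 2 distinct pairs, or identical times) yields the
    identity map.
    """
    pairs = np.asarray(ref_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("ref_pairs must be (n, 2): (reference time, sample time)")
    t_ref, t_samp = pairs[:, 0], pairs[:, 1]
    order = np.argsort(t_ref, kind="stable")
    t_ref, t_samp = t_ref[order], t_samp[order]
    if np.unique(t_ref).size < 2 or np.allclose(t_samp, t_samp[0]):
        return RTMap.identity(sample_id)
    if frac is None:
        frac = float(min(1.0, max(0.3, 8.0 / t_ref.size)))
    fitted = lowess(t_samp, t_ref, frac=frac, it=2, return_sorted=False)
    fitted = IsotonicRegression(increasing=True).fit_transform(t_ref, fitted)
    # collapse duplicate reference nodes for strict interpolation
    uniq_ref, idx = np.unique(t_ref, return_index=True)
    nodes_samp = np.maximum.accumulate(fitted[idx])
    return RTMap(sample_id, sample_nodes=nodes_samp, reference_nodes=uniq_ref)


def select_reference_peaks(
    grid: MassGrid,
    per_sample_tracks,
    scan_times,
    max_refs: int = 100,
    min_refs: int = 10,
    params: PeakParams | None = None,
):
    """Pick alignment reference rows: present in all samples, exactly one
    high-quality peak (shape >= 0.8, SNR >= 10 by default) on every
    sample's track. Returns a list of (row index, per-sample apex-time
    array); at most ``max_refs`` rows, spread across the RT range. Fewer
    than ``min_refs`` qualifying rows raises a warning and returns []
    (callers fall back to identity maps)."""
    params = params or REFERENCE_PEAK_PARAMS
    n_samples = len(per_sample_tracks)
    refs = []
    for r in range(grid.n_rows):
        members = grid.members[r]
        if np.any(members < 0):
            continue
        apexes = np.empty(n_samples)
        ok = True
        for s in range(n_samples):
            track = per_sample_tracks[s][members[s]]
            found = detect_peaks_on_array(
                track.intensities, scan_times[s], params=params, row_id=r
            )
            if len(found) != 1:
                ok = False
                break
            apexes[s] = found[0].apex_time
        if ok:
            refs.append((r, apexes))
    if len(refs) < min_refs:
        warnings.warn(
            f"only {len(refs)} qualifying reference rows (< {min_refs}); "
            "falling back to identity RT maps",
            stacklevel=2,
        )
        return []
    if len(refs) > max_refs:
        # spread across the RT range: sort by mean apex, take even strides
        refs.sort(key=lambda r: float(np.mean(r[1])))
        take = np.linspace(0, len(refs) - 1, max_refs).round().astype(int)
        refs = [refs[i] for i in sorted(set(take))]
    return refs


def fit_experiment_rt_maps(
    grid: MassGrid,
    per_sample_tracks,
    scan_times,
    frac: float | None = None,
    max_refs: int = 100,
    min_refs: int = 10,
) -> tuple[list[RTMap], int]:
    """Select references, choose the reference sample, and fit one RTMap
    per sample. Returns (maps, reference sample index).

    The reference sample is the one with the most qualifying reference
    peaks overall; here every qualifying row spans all samples, so the
    tie-break is the sample with the median total RT span — in practice
    the first sample. The reference sample's map is the identity.
    """
    refs = select_reference_peaks(
        grid, per_sample_tracks, scan_times, max_refs=max_refs, min_refs=min_refs
    )
    n_samples = len(per_sample_tracks)
    sample_ids = grid.sample_ids
    if not refs:
        return [RTMap.identity(s) for s in sample_ids], 0
    ref_sample = 0
    maps: list[RTMap] = []
    for s in range(n_samples):
        if s == ref_sample:
            maps.append(RTMap.identity(sample_ids[s]))
            continue
        pairs = [(apexes[ref_sample], apexes[s]) for _, apexes in refs]
        maps.append(fit_rt_map(pairs, frac=frac, sample_id=sample_ids[s]))
    return maps, ref_sample
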