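"""End-to-end processing: runs -> tracks -> MassGrid -> RT maps ->
composite tracks -> peaks -> feature table."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .composite import CompositeMassTrack, build_composites
from .features import FeatureTable, group_empirical_compounds, quantify
from .io_mzml import SampleRun
from .mass_grid import MassGrid, align_mass_grid
from .mass_tracks import build_mass_tracks
from .peaks import ElutionPeak, PeakParams, detect_peaks
from .rt_align import RTMap, fit_experiment_rt_maps

__all__ = ["RunConfig", "ExperimentResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunables of a processing run. The only parameter routinely
    worth touching is the mass resolution ``ppm`` (default 5)."""

    ppm: float = 5.0
    min_track_points: int = 6
    min_peak_height: float = 10_000.0
    min_peak_points: int = 6
    min_shape: float = 0.5
    min_snr: float = 3.0
    min_prominence_fraction: float = 0.1
    gap_scans: int = 3
    rt_tolerance_s: float = 6.0
    #: None = adaptive span (>= ~8 refs per window, floor 0.3)
    lowess_frac: float | None = None
    max_rt_refs: int = 100
    min_rt_refs: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("ppm", "min_peak_height", "min_shape", "min_snr",
                     "min_peak_points", "min_track_points", "rt_tolerance_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lowess_frac is not None and not 0 < self.lowess_frac <= 1:
            raise ValueError("lowess_frac must be in (0, 1]")

    def peak_params(self) -> PeakParams:
        return PeakParams(
            min_peak_height=self.min_peak_height,
            min_peak_points=self.min_peak_points,
            min_shape=self.min_shape,
            min_snr=self.min_snr,
            min_prominence_fraction=self.min_prominence_fraction,
            gap_scans=self.gap_scans,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentResult:
    config: RunConfig
    sample_ids: list[str]
    scan_times: list[np.ndarray] = field(repr=False)
    per_sample_tracks: list = field(repr=False)
    grid: MassGrid = None
    rt_maps: list[RTMap] = field(default_factory=list, repr=False)
    reference_sample: int = 0
    composites: list[CompositeMassTrack] = field(default_factory=list, repr=False)
    composite_peaks: list[tuple[CompositeMassTrack, ElutionPeak]] = field(
        default_factory=list, repr=False
    )
    table: FeatureTable = None
    empirical_compounds: dict[str, list[str]] = field(default_factory=dict)


def run_pipeline(runs: list[SampleRun], config: RunConfig | None = None) -> ExperimentResult:
    """Process centroided runs into a quantified feature table.

    Steps: per-sample mass tracks; cross-sample m/z alignment (MassGrid);
    LOWESS RT maps from high-quality single-peak reference rows; composite
    mass tracks on the reference time base; one-pass peak detection on the
    composites; per-sample quantification by inverse-mapped boundary
    lookup; empirical-compound grouping of isotope/adduct pairs.
    """
    if not runs:
        raise ValueError("need at least one sample run")
    config = config or RunConfig()
    config.validate()
    scan_times = [r.scan_times for r in runs]
    per_sample_tracks = [
        build_mass_tracks(r, ppm=config.ppm, min_track_points=config.min_track_points)
        for r in runs
    ]
    grid = align_mass_grid(per_sample_tracks, ppm=config.ppm)
    rt_maps, ref_sample = fit_experiment_rt_maps(
        grid, per_sample_tracks, scan_times,
        frac=config.lowess_frac, max_refs=config.max_rt_refs,
        min_refs=config.min_rt_refs,
    )
    composites = build_composites(
        grid, per_sample_tracks, rt_maps, scan_times, reference_sample=ref_sample
    )
    params = config.peak_params()
    composite_peaks = []
    for ctrack in composites:
        for peak in detect_peaks(ctrack, params=params):
            composite_peaks.append((ctrack, peak))
    table = quantify(
        composite_peaks, grid, per_sample_tracks, rt_maps, scan_times, ppm=config.ppm
    )
    groups = group_empirical_compounds(
        table, ppm=config.ppm, rt_tolerance_s=config.rt_tolerance_s
    )
    return ExperimentResult(
        config=config,
        sample_ids=[r.sample_id for r in runs],
        scan_times=scan_times,
        per_sample_tracks=per_sample_tracks,
        grid=grid,
        rt_maps=rt_maps,
        reference_sample=ref_sample,
        composites=composites,
        composite_peaks=composite_peaks,
        table=table,
        empirical_compounds=groups,
    )
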