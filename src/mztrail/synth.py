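"""Ground-truth synthetic LC-MS experiments.

The generator emits multi-sample centroided runs from a known compound
list: Gaussian elution peaks of varying height and width, per-scan
centroid m/z jitter at a stated ppm scale, smooth inter-sample RT drift,
optional additive per-track baseline, optional random noise centroids,
and compounds deliberately missing from subsets of samples. Identical
seeds yield identical runs (and byte-identical mzML files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_mzml import SampleRun, write_mzml
from .mass_grid import DELTA_C13, DELTA_NAH

__all__ = [
    "Compound",
    "GroundTruth",
    "SyntheticExperiment",
    "make_ground_truth",
    "add_partners",
    "generate_experiment",
    "write_experiment",
    "match_features",
]

#: centroids below this intensity are not emitted — real centroiding
#: thresholds away the faintest signals
INTENSITY_FLOOR = 100.0


@dataclass
class Compound:
    mz: float
    rt_center: float          # seconds, on the undrifted (reference) time axis
    sigma_s: float            # Gaussian elution width, seconds
    heights: np.ndarray       # apex height per sample
    present: np.ndarray       # bool mask per sample
    baseline: float = 0.0     # additive flat background on this track
    partner_of: int | None = None  # index of the parent compound, if any
    partner_kind: str | None = None  # "C13" or "NaH"


@dataclass
class GroundTruth:
    compounds: list[Compound]
    drift_amplitude_s: np.ndarray  # per-sample signed amplitude, seconds
    drift_phase: np.ndarray        # per-sample phase, radians
    ppm_jitter: float
    noise_rate: float              # expected random noise centroids per scan
    noise_intensity_scale: float
    seed: int
    rt_span_s: float = 300.0

    @property
    def n_samples(self) -> int:
        return len(self.drift_amplitude_s)

    def drift(self, sample: int, t, total_time: float):
        """Smooth slow drift (half a sine period over the run), seconds."""
        a = self.drift_amplitude_s[sample]
        return a * np.sin(
            np.pi * np.asarray(t, dtype=float) / total_time + self.drift_phase[sample]
        )


@dataclass
class SyntheticExperiment:
    runs: list[SampleRun]
    truth: GroundTruth
    true_areas: np.ndarray        # (n_compounds, n_samples) summed emitted intensity
    true_apex_times: np.ndarray   # (n_compounds, n_samples) drifted apex, seconds


def make_ground_truth(
    n_compounds: int = 100,
    n_samples: int = 5,
    seed: int = 0,
    mz_range: tuple[float, float] = (100.0, 900.0),
    min_mz_separation_ppm: float = 20.0,
    rt_span_s: float = 300.0,
    sigma_range_s: tuple[float, float] = (3.0, 8.0),
    height_range: tuple[float, float] = (5e4, 2e6),
    height_cv: float = 0.2,
    ppm_jitter: float = 1.0,
    drift_amplitude_s: float = 5.0,
    missing_fraction: float = 0.0,
    noise_rate: float = 0.0,
    noise_intensity_scale: float = 500.0,
    baseline_level: float = 0.0,
) -> GroundTruth:
    """Draw a random ground truth.

    Compound m/z values are mutually separated by at least
    ``min_mz_separation_ppm`` so each maps to its own mass track; heights
    are log-uniform across ``height_range`` with lognormal inter-sample
    variation (CV ~ ``height_cv``); apexes sit in the central 70% of the
    RT span; drift amplitudes are drawn up to ``drift_amplitude_s`` (the
    first sample is undrifted and serves naturally as reference).
    """
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    while len(mzs) < n_compounds:
        cand = float(rng.uniform(*mz_range))
        if all(abs(cand - m) > min_mz_separation_ppm * 1e-6 * max(cand, m) for m in mzs):
            mzs.append(cand)
    mzs.sort()
    compounds = []
    for mz in mzs:
        base_h = float(np.exp(rng.uniform(np.log(height_range[0]), np.log(height_range[1]))))
        heights = base_h * np.exp(rng.normal(0.0, height_cv, n_samples))
        present = rng.random(n_samples) >= missing_fraction
        if not present.any():
            present[int(rng.integers(n_samples))] = True
        compounds.append(
            Compound(
                mz=mz,
                rt_center=float(rng.uniform(0.15, 0.85) * rt_span_s),
                sigma_s=float(rng.uniform(*sigma_range_s)),
                heights=heights,
                present=present,
                baseline=baseline_level,
            )
        )
    amp = rng.uniform(-drift_amplitude_s, drift_amplitude_s, n_samples)
    amp[0] = 0.0
    phase = rng.uniform(0.0, np.pi / 4, n_samples)
    return GroundTruth(
        compounds=compounds,
        drift_amplitude_s=amp,
        drift_phase=phase,
        ppm_jitter=ppm_jitter,
        noise_rate=noise_rate,
        noise_intensity_scale=noise_intensity_scale,
        seed=seed,
        rt_span_s=rt_span_s,
    )


def add_partners(
    truth: GroundTruth,
    kind: str = "C13",
    ratio: float = 0.1,
    every: int = 1,
) -> GroundTruth:
    """Add an isotope (13C) or adduct (Na/H) partner to every ``every``-th
    compound, co-eluting at ``ratio`` x the parent height."""
    delta = {"C13": DELTA_C13, "NaH": DELTA_NAH}[kind]
    new = []
    for i, c in enumerate(truth.compounds):
        if c.partner_of is None and i % every == 0:
            new.append(
                Compound(
                    mz=c.mz + delta,
                    rt_center=c.rt_center,
                    sigma_s=c.sigma_s,
                    heights=c.heights * ratio,
                    present=c.present.copy(),
                    baseline=0.0,
                    partner_of=i,
                    partner_kind=kind,
                )
            )
    truth.compounds.extend(new)
    return truth


def generate_experiment(
    truth: GroundTruth,
    n_scans: int | None = None,
    scan_interval_s: float = 1.0,
) -> SyntheticExperiment:
    """Render a ground truth into centroided SampleRuns.

    Per sample and scan, each present compound contributes one centroid at
    mz x (1 + N(0, ppm_jitter x 1e-6)) with intensity height x Gaussian
    profile (plus its baseline), dropped below the intensity floor.
    Noise centroids arrive Poisson(noise_rate) per scan, uniform in m/z,
    exponential in intensity. Deterministic under the truth's seed.
    """
    if n_scans is None:
        n_scans = int(np.ceil(truth.rt_span_s / scan_interval_s))
    if n_scans < 20:
        raise ValueError("n_scans must be >= 20")
    n_comp = len(truth.compounds)
    n_samples = truth.n_samples
    total_time = n_scans * scan_interval_s
    times = (np.arange(n_scans) + 1.0) * scan_interval_s
    mz_lo = min(c.mz for c in truth.compounds) - 2.0
    mz_hi = max(c.mz for c in truth.compounds) + 2.0

    runs = []
    areas = np.zeros((n_comp, n_samples))
    apex = np.zeros((n_comp, n_samples))
    for s in range(n_samples):
        rng = np.random.default_rng([truth.seed, s])
        # per-compound drifted apex and full intensity profile
        profiles = np.zeros((n_comp, n_scans))
        for ci, c in enumerate(truth.compounds):
            shift = float(truth.drift(s, c.rt_center, total_time))
            apex[ci, s] = c.rt_center + shift
            if not c.present[s]:
                continue
            prof = c.heights[s] * np.exp(
                -((times - apex[ci, s]) ** 2) / (2.0 * c.sigma_s**2)
            )
            prof = prof + c.baseline
            prof[prof < INTENSITY_FLOOR] = 0.0
            profiles[ci] = prof
            areas[ci, s] = prof.sum()
        scans = []
        for k in range(n_scans):
            mzv, intv = [], []
            live = np.flatnonzero(profiles[:, k] > 0)
            if live.size:
                jitter = rng.normal(0.0, truth.ppm_jitter * 1e-6, live.size)
                for j, ci in enumerate(live):
                    mzv.append(truth.compounds[ci].mz * (1.0 + jitter[j]))
                    intv.append(profiles[ci, k])
            n_noise = rng.poisson(truth.noise_rate) if truth.noise_rate > 0 else 0
            for _ in range(n_noise):
                mzv.append(float(rng.uniform(mz_lo, mz_hi)))
                intv.append(float(rng.exponential(truth.noise_intensity_scale))
                            + INTENSITY_FLOOR)
            order = np.argsort(mzv) if mzv else []
            scans.append(
                (np.asarray(mzv, dtype=float)[order] if len(mzv) else np.empty(0),
                 np.asarray(intv, dtype=float)[order] if len(intv) else np.empty(0))
            )
        runs.append(SampleRun(f"S{s + 1}", times.copy(), scans))
    return SyntheticExperiment(runs, truth, areas, apex)


def write_experiment(exp: SyntheticExperiment, outdir) -> list[Path]:
    """Write each run as mzML plus the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in exp.runs:
        paths.append(write_mzml(run, outdir / f"{run.sample_id}.mzML"))
    truth = exp.truth
    doc = {
        "seed": truth.seed,
        "ppm_jitter": truth.ppm_jitter,
        "noise_rate": truth.noise_rate,
        "drift_amplitude_s": truth.drift_amplitude_s.tolist(),
        "drift_phase": truth.drift_phase.tolist(),
        "compounds": [
            {
                "mz": c.mz,
                "rt_center": c.rt_center,
                "sigma_s": c.sigma_s,
                "heights": np.asarray(c.heights).tolist(),
                "present": np.asarray(c.present).astype(bool).tolist(),
                "baseline": c.baseline,
                "partner_of": c.partner_of,
                "partner_kind": c.partner_kind,
            }
            for c in truth.compounds
        ],
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    return paths


def match_features(table, truth: GroundTruth, ppm: float = 5.0,
                   rt_tolerance_s: float = 6.0) -> dict[int, object]:
    """Match ground-truth compounds to reported features within the ppm /
    RT windows. Returns {compound index: Feature} for hits; recall is
    len(result) / n_compounds."""
    hits = {}
    for ci, c in enumerate(truth.compounds):
        best, best_d = None, None
        for f in table.features:
            if abs(f.mz - c.mz) > ppm * 1e-6 * c.mz:
                continue
            d = abs(f.rt_apex - c.rt_center)
            if d <= rt_tolerance_s and (best is None or d < best_d):
                best, best_d = f, d
        if best is not None:
            hits[ci] = best
    return hits
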