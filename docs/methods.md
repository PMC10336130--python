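# Methods

This note documents the models, algorithms, numerical choices and known
limitations of mztrail, in the spirit of the methods documentation of
packages like statsmodels or msprime.

## Pipeline model and assumptions

The central assumption is that on modern high-resolution instruments the
mass dimension is far more reliable than the chromatographic one, so
correspondence should be anchored in m/z first. Concretely:

- centroid m/z error is approximately Gaussian with a scale set by the
  instrument's ppm resolution, stable across the run;
- one chemical species produces at most one centroid per scan per
  sample, so a chromatogram ("mass track") is well defined once one
  value per scan is enforced;
- retention-time drift between samples is smooth and slowly varying —
  a monotone warp, not scan-to-scan scatter;
- elution peaks are approximately Gaussian; deviation from Gaussian
  shape is treated as evidence against a peak, not modeled further
  (alternatives like EMG change fitness scores only marginally and are
  deliberately out of scope).

## Mass tracks

All centroids of a run are pooled and sorted by m/z; the list is cut
wherever the gap between adjacent centroids exceeds `ppm × m/z`
(evaluated at the heavier member). Each group becomes one track:

- **Consensus m/z** is the intensity-weighted mean over *all* group
  members. Weighting privileges high-signal centroids, whose m/z is
  better determined. Displaced same-scan duplicates (below) still count
  toward the consensus — they measured the same species.
- **Same-scan collisions** inside a group are resolved by keeping the
  more intense centroid per scan (ties go to the centroid closer to the
  running consensus). The displaced centroids may seed their own track
  only if they form a ppm-coherent group of their own; otherwise a
  final uniqueness pass guarantees no two consensus m/z values of a
  sample lie within the tolerance.
- Tracks with fewer than `min_track_points = 6` nonzero scans are
  dropped: a track must at least be able to host a minimal peak.

Total intensity is conserved exactly by construction whenever no
same-scan collision occurs (collisions force a choice; the kept value
defines the track).

## MassGrid

The grid is seeded from the sample with the most tracks; the remaining
samples are folded in by reciprocal nearest neighbor within the ppm
window, in a canonical order (descending track count, sample id as
tie-break) that makes the result independent of input order. Tracks
participating in ¹³C/¹²C or Na/H anchor pairs are matched before the
rest: those spacings are chemically constrained and therefore
high-confidence guides. Unmatched tracks open new rows. Row consensus
m/z is a running intensity-weighted mean, finalized by one full
recompute; rows that end up closer than the tolerance are merged, so
the final grid obeys the mass resolution everywhere — equivalently,
every row has mSelectivity ≈ 1 at the working ppm unless the underlying
chemistry itself is ambiguous.

## RT alignment

Reference peaks are grid rows present in every sample whose track
carries exactly one detected peak at stringent thresholds (shape ≥ 0.8,
SNR ≥ 10). Requiring "the only peak on the track" removes any matching
ambiguity. Up to 100 references are kept, spread across the RT range;
below 10 the package warns and falls back to identity maps rather than
fit an unconstrained curve.

Per sample, LOWESS (2 robustifying iterations) regresses sample apex
time on reference apex time. The span is adaptive:
`frac = clip(8 / n_refs, 0.3, 1.0)` — each local window covers at least
~8 references, but never less than 30% of the range. A fixed wide span
(e.g. 0.5 with 100 references) incurs visible local-linear boundary
bias on curved drifts (>1 s at the range edges for a ±5 s sinusoidal
drift), while too narrow a span chases individual references; the
adaptive rule keeps the maximum recovery error under ~0.6 s across
10–100 references in our simulations. The fitted values are projected
onto the monotone cone by isotonic regression — a time map that runs
backwards is physically meaningless — and exposed as a piecewise-linear
bidirectional map; outside the calibrated range the boundary offset is
held constant.

Quantification reads only inverse-mapped boundaries, so residual
regression error widens composite peak windows slightly but cannot bias
per-sample values. RT alignment never touches the MassGrid.

## Composite mass tracks

Member tracks are remapped onto the reference time base (the reference
sample's scan times) by nearest-reference-scan assignment, then summed.
Nearest-scan assignment (rather than interpolation) conserves each
member's total intensity exactly. Two numerical details matter:

- the per-sample scan→bin assignment is made *strictly increasing*:
  scan rates match across samples, so the assignment is a
  near-bijection, and without this constraint two scans occasionally
  collapse into one bin while a neighbor stays empty, carving a
  spurious valley into an otherwise clean peak;
- even so, where a sample's drift crosses a scan boundary one reference
  bin receives no contribution from that sample (a ~1/N notch). For
  composites built through non-identity maps, peak detection therefore
  runs on a minimally smoothed copy (3-point moving average) of the
  signal; areas, shape, SNR and cSelectivity are always computed on the
  raw summed intensities.

## Peak detection

Per composite track:

1. **Statistics.** Baseline = 25th percentile of nonzero intensities;
   noise level = 1.4826 × MAD of the points at or below the baseline.
   Both are robust to peaks occupying a minority of scans. Smoothing
   (single pass, window 5) triggers when noise exceeds 5% of the track
   maximum — aggressive smoothing manufactures artifacts, so one mild
   pass only. Detrending triggers when the low quantile shifts across
   track thirds by more than max(3 × noise, 0.5 × baseline); the trend
   is a running-minimum envelope smoothed by a moving average.
2. **Segmentation.** Runs of signal above max(baseline, noise level),
   joined when separated by fewer than `gap_scans = 3` sub-threshold
   scans.
3. **Local-maximum search** per segment with height ≥ max(10 000,
   floor) and prominence ≥ 10% of the *segment* maximum — prominence is
   relative to local, not global, context, so small clean peaks survive
   next to large ones. Boundaries sit at the local minima between
   adjacent apexes and at segment edges.
4. **Filters.** Minimum 6 points; Gaussian shape ≥ 0.5 (Pearson r of
   the least-squares Gaussian fit against the data, clipped to [0, 1];
   non-convergence scores 0 — scale-free, unlike RMSE-based scores);
   SNR ≥ 3, computed with all surviving candidates masked out of the
   noise flanks.

Defaults (height 10 000, shape 0.5, SNR 3) sit between a permissive
screening configuration (≈5 000 / 0.1 / 1.1) and a stringent one
(height 10⁵); all are exposed in `PeakParams` / `RunConfig`.

## Quality metrics

- **SNR** = height / mean of up to 100 non-peak points per side, nearest
  first, points inside *any* retained peak excluded. The noise mean is
  floored at 1 count and the ratio capped at 1000 so noise-free
  synthetic tracks yield a finite, sortable value.
- **cSelectivity**: points above half the apex intensity, fraction
  inside any retained peak; boundary scans count as in-peak. The apex
  itself qualifies, so the denominator is never 0.
- **mSelectivity**: `score_i = max(0, 1 − Σ_{j≠i} exp(−Δ²/2σ_i²))`,
  `σ_i = ppm × m_i × 1e-6` per feature (ppm is relative by definition).
  Neighbors beyond 10σ contribute < 1e-21 and are skipped.

## Quantification and grouping

Per feature and sample, the composite boundary times are inverse-mapped
and the sample track summed over the window; a missing track gives area
0 with the detected flag false — absence in a sample is biology worth
reporting, not a reason to drop the feature. The detected flag
additionally requires the window maximum to reach 10% of
(composite height / n_samples). Degenerate features are grouped into
empirical compounds by connected components over ¹³C/¹²C and Na/H
spacings within ppm and 6 s of apex RT; this deliberately minimal
pairing stands in for full isotope/adduct network annotation, which
belongs to dedicated annotation tooling.

## Synthetic data: what it does and does not emulate

The generator draws compounds with log-uniform apex heights
(5×10⁴–2×10⁶ counts, lognormal ~20% CV across samples), Gaussian widths
3–8 s, apexes in the central 70% of a 300 s run at 1 Hz scans, m/z
100–900 with ≥20 ppm mutual separation, 1 ppm centroid jitter, and
per-sample smooth sinusoidal drift up to ±5 s (sample 1 undrifted).
Optional: random noise centroids (Poisson per scan, exponential
intensity), flat per-track baselines, missing-at-random compounds,
isotope/adduct partners at fixed height ratios. Centroids below 100
counts are not emitted, mimicking centroider thresholds. Identical
seeds give byte-identical mzML output.

Not emulated: chemical backgrounds with structure (column bleed
patterns), intensity-dependent m/z bias (the ppm scale is constant
rather than a polynomial function of m/z), saturated detectors, peak
tailing/fronting, co-eluting isomers on one track closer than the
track resolution, and profile-mode data. Passing tests on this
generator therefore demonstrate algorithmic correctness under the
stated error model, not instrument-specific robustness; the ≥20 ppm
compound separation in particular means cross-sample alignment is
exercised under clean conditions, with close-m/z stress cases covered
by dedicated fixtures rather than the default draw.

Simulation sizes used in the test suite (100 compounds × 5 samples ×
300 scans for recovery; smaller for unit scenarios) were chosen to
exercise every pipeline stage with comfortably repeatable statistics.

## Degenerate inputs and tie-breaks

- All-zero or empty tracks: zero statistics, no peaks, area 0.
- Fewer than 2 distinct RT reference pairs: identity map.
- Same-intensity same-scan centroid ties: closer-to-consensus wins.
- Grid row merge conflicts (one sample in both rows): the member track
  closer to the merged consensus is kept.
- Non-converging Gaussian fits score 0 rather than raising.

## Known limitations

- The ppm tolerance is a single global constant; data whose mass error
  grows across the m/z range would need the (unimplemented) polynomial
  error model.
- Tracks are an information-retrieval unit, not a claim that co-tracked
  species are one compound; isomers and sub-tolerance neighbors share a
  track by design.
- The composite approach assumes scan rates are comparable across
  samples; strongly heterogeneous scan grids would degrade the
  nearest-scan resampling.
- RT maps extrapolate with a constant offset beyond the reference
  range; drifts that accelerate outside it are not corrected there.
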