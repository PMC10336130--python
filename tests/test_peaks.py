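"""Peak detection: track statistics, smoothing, detrending, local-maximum
search with dynamic prominence, Gaussian shape scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mztrail as mt
from mztrail.peaks import PeakParams, _gaussian, detect_peaks_on_array
from conftest import gaussian_track


def _detect(vec, **kw):
    times = np.arange(float(len(vec)))
    return detect_peaks_on_array(np.asarray(vec, float), times, **kw)


class TestTrackStats:
    def test_flat_floor_plus_peak_recovers_baseline(self):
        vec = gaussian_track(500, 250, 4, 1e6, baseline=1000.0)
        stats = mt.estimate_track_stats(vec)
        assert stats.baseline == pytest.approx(1000.0, rel=0.1)

    def test_all_zero_track(self):
        stats = mt.estimate_track_stats(np.zeros(100))
        assert stats.baseline == 0 and stats.noise_level == 0
        assert _detect(np.zeros(100)) == []

    def test_white_noise_flags_smoothing_and_yields_no_peaks(self):
        rng = np.random.default_rng(13)
        vec = rng.uniform(0, 2000, 500)
        stats = mt.estimate_track_stats(vec)
        assert stats.needs_smoothing
        assert _detect(vec) == []


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(mt.smooth_track(np.full(20, 7.0), 5), 7.0)

    def test_unit_impulse_window3(self):
        x = np.zeros(9)
        x[4] = 1.0
        out = mt.smooth_track(x, 3)
        np.testing.assert_allclose(out[3:6], 1 / 3)
        assert out[0] == 0 and out[-1] == 0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=7, max_size=80),
           st.sampled_from([3, 5, 7]))
    def test_matches_brute_force_windowed_mean(self, values, window):
        x = np.asarray(values)
        out = mt.smooth_track(x, window)
        half = window // 2
        padded = np.pad(x, half, mode="reflect")
        expected = np.array(
            [padded[i : i + window].mean() for i in range(x.size)]
        )
        np.testing.assert_allclose(out, expected, rtol=1e-9, atol=1e-9)


class TestDetrend:
    def test_pure_ramp_removed(self):
        ramp = np.linspace(0, 5000, 300)
        out = mt.detrend_track(ramp)
        assert np.all(out <= np.max(ramp) * 0.1)

    def test_ramp_plus_peak_recovers_height(self):
        ramp = np.linspace(0, 5000, 300)
        vec = ramp + gaussian_track(300, 150, 5, 1e5)
        out = mt.detrend_track(vec)
        assert out.max() == pytest.approx(1e5, rel=0.1)
        assert abs(int(np.argmax(out)) - 150) <= 1

    def test_flat_track_nearly_unchanged(self):
        vec = np.full(200, 3000.0)
        out = mt.detrend_track(vec)
        # a flat background is its own trend; what's left is ~0
        assert np.all(out <= 1e-6)


class TestDetection:
    def test_single_clean_gaussian(self):
        vec = gaussian_track(300, 150, 4, 1e6)
        peaks = _detect(vec)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.apex_index == 150
        assert p.shape >= 0.95
        assert p.left_base <= 150 <= p.right_base

    def test_two_gaussians_eight_sigma_apart(self):
        vec = gaussian_track(400, 150, 5, 1e6) + gaussian_track(400, 190, 5, 8e5)
        peaks = _detect(vec)
        assert len(peaks) == 2
        assert abs(peaks[0].apex_index - 150) <= 1
        assert abs(peaks[1].apex_index - 190) <= 1

    def test_small_peak_beside_big_peak_at_low_noise(self):
        vec = gaussian_track(600, 150, 5, 1e7) + gaussian_track(600, 400, 5, 5e4)
        peaks = _detect(vec, params=PeakParams(min_peak_height=10_000))
        apexes = sorted(p.apex_index for p in peaks)
        assert len(peaks) == 2 and abs(apexes[1] - 400) <= 1

    def test_noise_only_segments_give_no_peaks(self):
        """Dense unstructured noise — even well above the height threshold —
        is rejected by the SNR and shape gates."""
        for seed in (3, 7, 11):
            rng = np.random.default_rng(seed)
            vec = rng.uniform(0, 30000, 400)
            assert _detect(vec) == []

    def test_raising_min_height_never_adds_peaks(self):
        rng = np.random.default_rng(3)
        vec = sum(
            gaussian_track(500, c, 5, h)
            for c, h in zip(rng.uniform(30, 470, 6), rng.uniform(2e4, 1e6, 6))
        )
        counts = [
            len(_detect(vec, params=PeakParams(min_peak_height=h)))
            for h in (1e4, 5e4, 2e5, 1e6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_retained_peaks_do_not_overlap(self):
        rng = np.random.default_rng(19)
        vec = sum(
            gaussian_track(500, c, 4, h)
            for c, h in zip(rng.uniform(30, 470, 8), rng.uniform(5e4, 1e6, 8))
        )
        peaks = _detect(vec)
        spans = sorted((p.left_base, p.right_base) for p in peaks)
        for (l1, r1), (l2, r2) in zip(spans, spans[1:]):
            assert r1 <= l2

    def test_no_retained_peak_below_min_shape(self):
        rng = np.random.default_rng(23)
        vec = gaussian_track(400, 100, 5, 8e5) + rng.exponential(2e4, 400)
        for p in _detect(vec):
            assert p.shape >= 0.5

    def test_composite_of_identical_samples_same_apexes(self):
        vec = gaussian_track(300, 80, 4, 2e5) + gaussian_track(300, 200, 6, 6e5)
        one = {p.apex_index for p in _detect(vec)}
        five = {p.apex_index for p in _detect(5 * vec)}
        assert one == five
        h1 = {p.apex_index: p.height for p in _detect(vec)}
        h5 = {p.apex_index: p.height for p in _detect(5 * vec)}
        for k in one:
            assert h5[k] == pytest.approx(5 * h1[k], rel=0.01)


class TestGaussianShape:
    def test_exact_gaussian_scores_near_one(self):
        vec = gaussian_track(100, 50, 6, 1e5)
        assert mt.gaussian_shape(vec, 30, 70) >= 0.999

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(31)
        vec = rng.uniform(0, 1e4, 60)
        assert mt.gaussian_shape(vec, 5, 55) < 0.5

    def test_triangle_matches_grid_search_oracle(self):
        tri = np.concatenate([np.linspace(0, 1e5, 12), np.linspace(1e5, 0, 12)[1:]])
        score = mt.gaussian_shape(tri, 0, tri.size - 1)
        # independent oracle: dense grid search over (amplitude, center, width)
        t = np.arange(tri.size, dtype=float)
        best = 0.0
        for a in np.linspace(0.5e5, 2e5, 40):
            for mu in np.linspace(5, 18, 40):
                for sig in np.linspace(1, 15, 40):
                    fit = _gaussian(t, a, mu, sig)
                    if np.std(fit) == 0:
                        continue
                    r = np.corrcoef(fit, tri)[0, 1]
                    best = max(best, min(max(r, 0.0), 1.0))
        assert score == pytest.approx(best, abs=0.02)
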