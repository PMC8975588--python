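"""Unit tests of the TKEO detection chain and dynamic-threshold segmentation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from ehgkit.detect import (
    DetectionConfig,
    EnergyTrace,
    TraceStage,
    combine_channels,
    detect_contractions,
    detrend_linear,
    dynamic_threshold,
    envelope,
    estimate_baseline_mask,
    gaussian_smooth,
    running_mean,
    segment_contractions,
    tkeo,
    zscore_energy,
)
from ehgkit.io import EHGRecord
from ehgkit.synth import SynthSpec, generate_record

FS = 20.0


class TestRunningMean:
    def test_constant_preserved(self):
        np.testing.assert_allclose(running_mean(np.full(50, 3.7), 0.5, FS), 3.7)

    def test_truncated_edges_hand_computed(self):
        out = running_mean(np.array([0.0, 3.0, 0.0]), window_s=3 / FS, fs=FS)
        np.testing.assert_allclose(out, [1.5, 1.0, 1.5])

    def test_single_sample_window_is_identity(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_array_equal(running_mean(x, 1 / FS, FS), x)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            running_mean(np.array([]), 0.5, FS)


class TestDetrend:
    def test_ramp_removed_exactly(self):
        t = np.arange(200.0)
        assert np.max(np.abs(detrend_linear(2.5 * t + 7.0))) < 1e-9

    def test_constant_removed(self):
        assert np.max(np.abs(detrend_linear(np.full(100, 4.0)))) < 1e-12

    def test_matches_least_squares_oracle(self, rng):
        x = rng.standard_normal(500)
        t = np.arange(500.0)
        coef = np.polyfit(t, x, 1)
        np.testing.assert_allclose(detrend_linear(x), x - np.polyval(coef, t), atol=1e-10)


class TestTkeo:
    def test_interior_matches_brute_force_exactly(self, rng):
        for lag in (1, 2, 5):
            x = rng.standard_normal(200)
            y = tkeo(x, lag)
            for t in range(lag, 200 - lag):
                assert y[t] == x[t] ** 2 - x[t - lag] * x[t + lag]

    def test_constant_is_zero(self):
        np.testing.assert_array_equal(tkeo(np.full(20, 3.0)), 0.0)

    def test_unit_impulse(self):
        assert tkeo(np.array([0.0, 1.0, 0.0]))[1] == 1.0

    def test_sinusoid_closed_form(self):
        # x_t = A sin(w t) gives y_t = A^2 sin^2(w) at every interior sample
        for A, w in [(1.0, 0.3), (2.5, 1.1), (0.3, 0.02)]:
            t = np.arange(500)
            y = tkeo(A * np.sin(w * t))
            assert np.max(np.abs(y[1:-1] - A**2 * np.sin(w) ** 2)) < 1e-9

    def test_edges_replicated_and_errors(self):
        y = tkeo(np.arange(10.0), lag=2)
        assert y[0] == y[1] == y[2] and y[-1] == y[-2] == y[-3]
        with pytest.raises(ValueError):
            tkeo(np.arange(10.0), lag=0)
        with pytest.raises(ValueError):
            tkeo(np.arange(4.0), lag=2)


class TestBaselineAndZscore:
    def test_quantile_one_masks_everything(self, rng):
        e = rng.standard_normal(100) ** 2
        assert estimate_baseline_mask(e, 1.0).all()

    def test_bimodal_mask_covers_floor_only(self):
        e = np.concatenate([np.full(200, 1.0), np.full(100, 50.0), np.full(200, 1.0)])
        mask = estimate_baseline_mask(e, 0.5)
        assert mask[:200].all() and mask[-200:].all()
        assert not mask[200:300].any()

    def test_zero_quantile_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_baseline_mask(rng.standard_normal(10) ** 2, 0.0)

    def test_zscore_arithmetic(self):
        e = np.array([1.0, 3.0, 5.0])  # baseline mean 2, population sd 1
        trace = zscore_energy(e, np.array([True, True, False]), FS)
        assert trace.baseline_mu == pytest.approx(2.0)
        assert trace.baseline_sigma == pytest.approx(1.0)
        assert trace.values[2] == pytest.approx(3.0)

    def test_full_mask_equals_classical_standardization(self, rng):
        e = rng.standard_normal(300) ** 2
        z = zscore_energy(e, np.ones(300, bool), FS).values
        np.testing.assert_allclose(z, (e - e.mean()) / e.std(), atol=1e-12)

    def test_zero_baseline_variance_advises(self):
        with pytest.raises(ValueError, match="baseline"):
            zscore_energy(np.array([1.0, 1.0, 5.0]), np.array([True, True, False]), FS)


class TestSmoothEnvelopeCombine:
    def _trace(self, values):
        return EnergyTrace(values, FS, TraceStage.zscored, 0.0, 1.0)

    def test_constant_unchanged_by_smoothing(self):
        out = gaussian_smooth(self._trace(np.full(200, 2.0)), 2.0)
        np.testing.assert_allclose(out.values, 2.0)

    def test_impulse_gives_gaussian_kernel(self):
        n, sigma_s = 401, 0.5
        x = np.zeros(n)
        x[n // 2] = 1.0
        out = gaussian_smooth(self._trace(x), sigma_s).values
        sigma = sigma_s * FS
        radius = int(4 * sigma + 0.5)  # kernel support is truncated at 4 sigma
        t = np.arange(-radius, radius + 1)
        kernel = np.exp(-(t**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        np.testing.assert_allclose(
            out[n // 2 - radius : n // 2 + radius + 1], kernel, atol=1e-12
        )
        assert np.all(out[: n // 2 - radius] == 0)

    def test_sum_preserved(self, rng):
        x = rng.standard_normal(4000) ** 2
        out = gaussian_smooth(self._trace(x), 2.0).values
        assert abs(out.sum() - x.sum()) / x.sum() < 1e-3

    def test_tiny_sigma_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_allclose(gaussian_smooth(self._trace(x), 1e-9).values, x, atol=1e-9)

    def test_envelope_of_sinusoid_is_amplitude(self):
        t = np.arange(2000) / FS
        out = envelope(self._trace(3.0 * np.sin(2 * np.pi * 0.5 * t))).values
        interior = out[200:-200]
        np.testing.assert_allclose(interior, 3.0, rtol=0.01)

    def test_envelope_nonnegative_and_zero(self, rng):
        assert (envelope(self._trace(rng.standard_normal(256))).values >= 0).all()
        np.testing.assert_allclose(envelope(self._trace(np.zeros(64))).values, 0.0)

    def test_combine_single_channel_identity(self, rng):
        x = np.abs(rng.standard_normal(50))
        np.testing.assert_allclose(combine_channels([x]), x)

    def test_combine_constants(self):
        out = combine_channels([np.full(10, 3.0), np.full(10, 4.0)])
        np.testing.assert_allclose(out, np.sqrt(12.5))

    def test_combine_zeros(self):
        np.testing.assert_allclose(combine_channels([np.zeros(10), np.zeros(10)]), 0.0)


class TestDynamicThreshold:
    CFG = DetectionConfig()  # taper off by default

    def test_printed_formula_arithmetic(self):
        # lowest 10% are zeros, min 0, max 10 -> 1.2 * (0 + 0.25 * 10) = 3.0
        values = np.concatenate([np.zeros(10), np.linspace(0.5, 10, 90)])
        assert dynamic_threshold(values, self.CFG) == pytest.approx(3.0)

    def test_constant_degenerates_to_basal(self):
        assert dynamic_threshold(np.full(100, 2.0), self.CFG) == pytest.approx(1.2 * 2.0)

    def test_homogeneity(self, rng):
        v = np.abs(rng.standard_normal(500))
        thr = dynamic_threshold(v, self.CFG)
        assert dynamic_threshold(7.0 * v, self.CFG) == pytest.approx(7.0 * thr)

    def test_hann_taper_lowers_basal(self, rng):
        v = np.abs(rng.standard_normal(500)) + 1.0
        tapered = dynamic_threshold(v, DetectionConfig(taper="hann"))
        assert tapered < dynamic_threshold(v, self.CFG)


def _quiet_floor(rng, n, level=1.0, jitter=0.01):
    return level + jitter * rng.standard_normal(n)


class TestSegmentation:
    def test_flat_signal_yields_nothing(self):
        assert len(segment_contractions(np.full(12000, 2.0), FS)) == 0

    def test_single_burst_recovered(self, rng):
        n = int(600 * FS)
        x = _quiet_floor(rng, n)
        a, b = int(300 * FS), int(330 * FS)
        x[a:b] += 10.0
        found = segment_contractions(x, FS)
        assert len(found) == 1
        from ehgkit.io import ContractionInterval

        assert found[0].iou(ContractionInterval(300, 330)) >= 0.8
        assert found[0].score == pytest.approx(x[a:b].max())

    def test_duration_filter_strictness(self, rng):
        n = int(600 * FS)
        for dur, expected in [(8, 0), (12, 1)]:
            x = _quiet_floor(rng, n)
            a = int(100 * FS)
            x[a : a + int(dur * FS)] += 10.0
            assert len(segment_contractions(x, FS)) == expected

    def test_intervals_sorted_disjoint_and_long_enough(self, rng):
        cfg = DetectionConfig()
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = _quiet_floor(r, int(900 * FS))
            for start in r.uniform(30, 850, size=4):
                a = int(start * FS)
                x[a : a + int(r.uniform(5, 40) * FS)] += r.uniform(5, 15)
            found = segment_contractions(x, FS, cfg)
            for iv in found:
                assert iv.duration_s > cfg.min_duration_s
            for u, v in zip(found, found[1:]):
                assert u.end_s <= v.start_s


class TestDetectEndToEnd:
    def test_deterministic(self, short_synth):
        record, _ = short_synth
        a = detect_contractions(record)
        b = detect_contractions(record)
        assert [(iv.start_s, iv.end_s) for iv in a] == [(iv.start_s, iv.end_s) for iv in b]

    def test_amplitude_scale_covariance(self, short_synth):
        record, _ = short_synth
        scaled = EHGRecord(record.signals * 2.0, record.fs, record.channel_labels)
        a = detect_contractions(record)
        b = detect_contractions(scaled)
        assert len(a) == len(b)
        for u, v in zip(a, b):
            assert abs(u.start_s - v.start_s) <= 2 / record.fs
            assert abs(u.end_s - v.end_s) <= 2 / record.fs

    def test_high_snr_bursts_all_recovered(self):
        record, truth = generate_record(SynthSpec(duration_s=1800, n_bursts=6, seed=5))
        found = detect_contractions(record)
        for true_iv in truth.intervals:
            assert max(d.iou(true_iv) for d in found) >= 0.5
        # genuine bursts are cleanly separated by score from any noise ridges
        top6 = sorted(found, key=lambda d: d.score, reverse=True)[:6]
        for true_iv in truth.intervals:
            assert max(d.iou(true_iv) for d in top6) >= 0.5

    def test_noise_detections_score_far_below_bursts(self, rng, short_synth):
        # On activity-free noise the dynamic threshold sits inside the floor, so
        # occasional >10 s ridges are flagged; their peak scores stay orders of
        # magnitude below genuine burst scores, which is what the score reports.
        noise_rec = EHGRecord(rng.standard_normal((7, int(600 * FS))) * 5, fs=FS)
        noise_scores = [iv.score for iv in detect_contractions(noise_rec)]
        record, _ = short_synth
        burst_scores = [iv.score for iv in detect_contractions(record)]
        assert burst_scores
        if noise_scores:
            assert max(noise_scores) < 0.2 * min(burst_scores)
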