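"""Feature registry and per-window computations."""

import numpy as np
import pytest

from bradyflux.features import (
    FEATURE_NAMES,
    FEATURE_REGISTRY,
    MAIN_FEATURES,
    coefficient_of_variation,
    extract_features,
    segment_windows,
    spectral_features,
    temporal_features,
)
from conftest import make_processed


class TestRegistry:
    def test_total_is_103(self):
        assert len(FEATURE_REGISTRY) == 103
        assert len(set(FEATURE_NAMES)) == 103

    def test_main_features_on_vector_magnitude(self):
        assert set(MAIN_FEATURES) <= set(FEATURE_NAMES)
        assert all(name.startswith("svm_") for name in MAIN_FEATURES)

    def test_per_axis_blocks_identical_composition(self):
        def block(channel):
            return sorted(
                comp for _, chan, comp in FEATURE_REGISTRY
                if chan == channel and not comp.startswith(("sma", "autocorr", "crossings"))
            )

        assert block("x") == block("y") == block("z") == block("svm")


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration_s,window_s,expected",
        [(3600, 60, 60), (3570, 60, 59), (59, 60, 0)],
    )
    def test_window_counts(self, duration_s, window_s, expected):
        spans = segment_windows(duration_s * 120, window_s, 120.0)
        assert len(spans) == expected
        if spans:
            starts, stops = zip(*spans)
            assert starts[0] == 0
            assert all(b - a == window_s * 120 for a, b in spans)
            assert list(stops[:-1]) == list(starts[1:])  # contiguous

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(1000, 0.01, 120.0)


class TestCov:
    def test_hand_computed_value(self):
        # population sd of [1,1,1,3] is 0.8660, mean 1.5
        assert coefficient_of_variation(np.array([1.0, 1.0, 1.0, 3.0])) == pytest.approx(
            0.57735, abs=1e-4
        )

    def test_constant_is_zero(self):
        assert coefficient_of_variation(np.full(10, 4.2)) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.random(100) + 1.0
        assert coefficient_of_variation(3.7 * s) == pytest.approx(
            coefficient_of_variation(s), rel=1e-12
        )

    def test_zero_mean_sentinel_and_empty(self):
        assert coefficient_of_variation(np.array([-1.0, 1.0])) == np.inf
        with pytest.raises(ValueError):
            coefficient_of_variation(np.array([]))


class TestTemporal:
    def test_constant_series_degenerate_values(self):
        f = temporal_features(np.full(960, 2.0), 120.0)
        assert f["variance"] == 0.0
        assert f["n_peaks"] == 0.0
        assert f["jerk_rms"] == 0.0
        assert f["cov"] == 0.0

    def test_two_hz_sinusoid_peak_count(self):
        t = np.arange(0, 60, 1 / 120)
        f = temporal_features(np.sin(2 * np.pi * 2.0 * t), 120.0)
        assert f["n_peaks"] == 120.0

    def test_range_max_min(self):
        s = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.5, 0.0])
        f = temporal_features(s, 120.0)
        assert f["max"] == 1.0 and f["min"] == 0.0 and f["range"] == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            temporal_features(np.zeros(5), 120.0)


class TestSpectral:
    def test_pure_tone_dominant_frequency(self):
        t = np.arange(0, 60, 1 / 120)
        f = spectral_features(np.sin(2 * np.pi * 2.0 * t), 120.0)
        df = 120.0 / 256
        assert abs(f["dom_freq"] - 2.0) <= df

    def test_white_noise_band_powers_proportional_to_bandwidth(self):
        """Flat-spectrum oracle: relative band powers match the fraction of
        Welch frequency bins in each band (bandwidth up to the 0.47 Hz bin
        quantization of 256-sample segments)."""
        rng = np.random.default_rng(11)
        f = spectral_features(rng.normal(0, 1, 120 * 600), 120.0)
        rel = np.array(
            [f["relpower_0p3_1"], f["relpower_1_2"], f["relpower_2_3"], f["relpower_3_4"]]
        )
        freqs = np.fft.rfftfreq(256, d=1 / 120.0)
        total = np.sum((freqs >= 0.3) & (freqs <= 4.0))
        expected = np.array(
            [np.sum((freqs >= lo) & (freqs < hi)) / total
             for lo, hi in ((0.3, 1), (1, 2), (2, 3), (3, 4))]
        )
        np.testing.assert_allclose(rel, expected, atol=0.03)
        assert rel.sum() == pytest.approx(1.0, abs=0.05)

    def test_two_tone_centroid(self):
        t = np.arange(0, 120, 1 / 120)
        s = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        f = spectral_features(s, 120.0)
        assert f["spec_centroid"] == pytest.approx(2.0, abs=0.1)
        assert f["median_freq"] == pytest.approx(2.0, abs=1.0)

    def test_all_zero_series_flagged_values(self):
        f = spectral_features(np.zeros(1000), 120.0)
        assert f["power_total"] == 0.0 and f["dom_freq"] == 0.0


class TestExtract:
    def test_window_rows_complete_and_finite(self, rng):
        rec = make_processed(*(rng.normal(0, 1, 120 * 130) for _ in range(3)))
        table = extract_features(rec, 60.0)
        assert len(table) == 2
        values = table[FEATURE_NAMES].to_numpy()
        assert values.shape == (2, 103)
        assert np.all(np.isfinite(values))

    def test_identical_windows_identical_features(self):
        one = np.sin(2 * np.pi * 1.5 * np.arange(0, 60, 1 / 120)) + 0.5
        rec = make_processed(one.tolist() * 2, one.tolist() * 2, one.tolist() * 2)
        table = extract_features(rec, 60.0)
        np.testing.assert_allclose(
            table.iloc[0][FEATURE_NAMES].to_numpy().astype(float),
            table.iloc[1][FEATURE_NAMES].to_numpy().astype(float),
            atol=1e-9,
        )

    def test_rest_window_near_zero_energy(self, rng):
        rec = make_processed(*(rng.normal(0, 0.01, 120 * 60) for _ in range(3)))
        row = extract_features(rec, 60.0).iloc[0]
        assert row["svm_rms"] < 0.05
        assert row["svm_power_total"] < 0.01

    def test_nonnegative_features(self, rng):
        rec = make_processed(*(rng.normal(0, 1, 120 * 60) for _ in range(3)))
        row = extract_features(rec, 60.0).iloc[0]
        for channel in ("x", "y", "z", "svm"):
            for comp in ("sd", "variance", "cov", "rms", "range", "iqr", "n_peaks",
                         "jerk_mean_abs", "jerk_rms", "power_total"):
                assert row[f"{channel}_{comp}"] >= 0

    def test_stationary_input_start_invariance(self, rng):
        """Feature values on white noise do not depend on the window's
        absolute position beyond sampling error."""
        series = rng.normal(0, 1, 120 * 240)
        rec = make_processed(series, series, series)
        table = extract_features(rec, 60.0)
        rms = table["svm_rms"].to_numpy()
        assert np.ptp(rms) < 0.1 * rms.mean()
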