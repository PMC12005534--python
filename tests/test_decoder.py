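"""Artifact blanking, MWP features, movement classifier, and decoder
trace measures."""

import numpy as np
import pytest
from scipy import signal

from intentchain.decoder_pipeline import (
    MovementClassifier,
    blank_artifacts,
    classify,
    decoder_auc,
    extract_mwp,
    objective_intention_time,
    surrogate_crossing_rate,
    threshold_crossing,
    timecourse_divergence,
    train_classifier,
    wavelet_level_band,
)
from intentchain.session_model import ContinuousTrace, TraceKind
from intentchain.synthetic_data import generate_calibration_features, generate_raw_snippet


def _trace(values, bin_ms=100.0, t0=0.0):
    return ContinuousTrace(
        kind=TraceKind.DECODER, fs_hz=1000.0 / bin_ms, t0_ms=t0, values=np.asarray(values, float)
    )


class TestBlanking:
    def test_clean_signal_unchanged(self, rng):
        raw = generate_raw_snippet(50.0, 16, rng)
        cleaned, intervals = blank_artifacts(raw.values, monitor_channels=np.arange(12))
        assert intervals == []
        np.testing.assert_array_equal(cleaned, raw.values)

    def test_artifact_on_five_monitored_channels_blanked(self, rng):
        raw = generate_raw_snippet(
            50.0, 16, rng, artifact_times_ms=np.array([20.0]),
            artifact_channels=np.arange(5),
        )
        cleaned, intervals = blank_artifacts(raw.values, monitor_channels=np.arange(12))
        assert len(intervals) == 1
        start, stop = intervals[0]
        assert stop - start == 105  # 3.5 ms at 30 kHz
        # blanked region no longer carries the 600 uV deflection
        assert np.abs(cleaned[:, start:stop]).max() < 500.0

    def test_artifact_on_three_channels_ignored(self, rng):
        raw = generate_raw_snippet(
            50.0, 16, rng, artifact_times_ms=np.array([20.0]),
            artifact_channels=np.arange(3),
        )
        cleaned, intervals = blank_artifacts(raw.values, monitor_channels=np.arange(12))
        assert intervals == []
        np.testing.assert_array_equal(cleaned, raw.values)

    def test_short_snippet_raises(self, rng):
        with pytest.raises(ValueError):
            blank_artifacts(rng.standard_normal((12, 50)), monitor_channels=np.arange(12))


class TestMwp:
    def test_level_band_edges(self):
        assert wavelet_level_band(30000.0, 6)[0] == pytest.approx(234.375)
        assert wavelet_level_band(30000.0, 3)[1] == pytest.approx(3750.0)

    def test_zero_signal_zero_features(self):
        feats = extract_mwp(np.zeros((2, 9000)), normalize=False)
        assert np.all(feats.values == 0.0)

    @pytest.mark.parametrize("tone_hz,level_idx", [(1400.0, 1), (600.0, 2)])
    def test_tone_energy_in_matching_level(self, tone_hz, level_idx):
        """A tone central to a detail band concentrates there, and a
        band-pass filter bank agrees on the dominant band (level 4 =
        937.5-1875 Hz, level 5 = 468.75-937.5 Hz)."""
        fs = 30000.0
        t = np.arange(int(0.3 * fs)) / fs
        x = np.sin(2 * np.pi * tone_hz * t)[None, :]
        per_level = []
        for lev in (3, 4, 5, 6):
            f = extract_mwp(x, levels=(lev,), normalize=False)
            per_level.append(f.values.mean())
        assert int(np.argmax(per_level)) == level_idx

        # oracle: band-pass energy per level band
        oracle = []
        for lev in (3, 4, 5, 6):
            lo, hi = wavelet_level_band(fs, lev)
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            oracle.append(np.mean(signal.sosfiltfilt(sos, x[0]) ** 2))
        assert int(np.argmax(oracle)) == level_idx

    def test_bin_count(self):
        feats = extract_mwp(np.random.default_rng(0).standard_normal((3, 30000)))
        assert feats.values.shape == (10, 3)  # 1 s at 100 ms bins


class TestClassifier:
    def test_separable_features_high_accuracy(self, rng):
        X, y = generate_calibration_features(rng)
        n = len(y)
        idx = rng.permutation(n)
        tr, te = idx[: int(0.7 * n)], idx[int(0.7 * n) :]
        model = train_classifier(X[tr], y[tr], random_state=0)
        assert model.score(X[te], y[te]) >= 0.95

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError):
            train_classifier(X, np.array(["rest"] * 20))

    def test_scores_bounded_and_deterministic(self, rng):
        X, y = generate_calibration_features(rng)
        model = train_classifier(X, y, random_state=0)
        s1 = model.decision_scores(X, "HC")
        s2 = model.decision_scores(X, "HC")
        np.testing.assert_array_equal(s1, s2)
        assert s1.min() >= -1.0 and s1.max() <= 1.0

    def test_rest_scores_negative_hc_scores_positive(self, rng):
        X, y = generate_calibration_features(rng, class_sep=3.0)
        model = train_classifier(X, y, random_state=0)
        s = model.decision_scores(X, "HC")
        assert np.median(s[y == "rest"]) < 0
        assert np.median(s[y == "HC"]) > 0

    def test_classify_emits_decoder_trace(self, rng):
        X, y = generate_calibration_features(rng)
        model = train_classifier(X, y, random_state=0)
        trace = classify(model, X[:20])
        assert trace.kind is TraceKind.DECODER
        assert trace.n_samples == 20

    def test_dimension_mismatch_raises(self, rng):
        X, y = generate_calibration_features(rng)
        model = train_classifier(X, y, random_state=0)
        with pytest.raises(ValueError):
            model.decision_scores(X[:, :10], "HC")

    def test_sklearn_get_params_roundtrip(self):
        m = MovementClassifier(sparsity=0.25, C=2.0)
        m2 = MovementClassifier(**m.get_params())
        assert m2.sparsity == 0.25 and m2.C == 2.0


class TestTraceMeasures:
    def test_all_negative_no_crossing(self):
        assert threshold_crossing(_trace([-0.5, -0.2, -0.9])) is None

    def test_crossing_bin_start_time(self):
        tr = _trace([-0.5, -0.1, 0.2, 0.5])
        assert threshold_crossing(tr) == pytest.approx(200.0)

    def test_positive_start_is_not_crossing(self):
        assert threshold_crossing(_trace([0.5, 0.6, 0.7])) is None

    def test_objective_intent_step(self):
        tr = _trace([-0.6] * 5 + [-0.1] + [0.5] * 4)
        t = objective_intention_time(tr, noise_mean=-0.6, noise_sd=0.05)
        assert t == pytest.approx(500.0)

    def test_objective_intent_none_and_zero_sd(self):
        tr = _trace([-0.6] * 10)
        assert objective_intention_time(tr, -0.6, 0.05) is None
        with pytest.raises(ValueError):
            objective_intention_time(tr, -0.6, 0.0)

    def test_auc_constants(self):
        assert decoder_auc(_trace(np.ones(50)), (0, 4900)) == pytest.approx(1.0)
        assert decoder_auc(_trace(-np.ones(50)), (0, 4900)) == pytest.approx(-1.0)

    def test_auc_matches_trapezoid_oracle(self, rng):
        v = rng.uniform(-1, 1, 80)
        tr = _trace(v)
        got = decoder_auc(tr, (0.0, 7900.0))
        t = np.arange(80) * 100.0
        oracle = 0.0
        for i in range(79):
            oracle += 0.5 * (v[i] + v[i + 1]) * (t[i + 1] - t[i])
        oracle /= t[-1] - t[0]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_auc_linearity(self, rng):
        v = rng.uniform(-1, 1, 50)
        for a in (0.5, -0.3, 1.0):
            assert decoder_auc(_trace(a * v), (0, 4900)) == pytest.approx(
                a * decoder_auc(_trace(v), (0, 4900)), abs=1e-12
            )

    def test_surrogate_rate_zero_when_never_crossing(self, rng):
        tr = _trace(-np.abs(rng.uniform(0.1, 1, 500)))
        rate = surrogate_crossing_rate(tr, [(0.0, 5000.0)], 50, rng)
        assert rate == 0.0

    def test_surrogate_rate_matches_enumeration(self):
        """Dense-shift oracle: for every possible window placement the
        hit indicator matches; random placements sample that population."""
        v = -np.ones(200)
        v[50] = 0.5  # one crossing at bin 50
        v[120] = 0.5  # and another at bin 120
        tr = _trace(v)
        t = tr.times_ms
        length = 3000.0
        starts = np.arange(t[0], t[-1] - length, 10.0)
        crossings = t[1:][(v[1:] >= 0) & (v[:-1] < 0)]
        hits = [
            np.any((crossings >= s) & (crossings < s + length)) for s in starts
        ]
        expected = np.mean(hits)
        rng = np.random.default_rng(0)
        rate = surrogate_crossing_rate(tr, [(0.0, length)], 4000, rng)
        assert rate == pytest.approx(expected, abs=0.03)


class TestDivergence:
    def test_identical_groups_nothing(self, rng):
        a = rng.standard_normal((10, 40))
        first, p = timecourse_divergence(a, a.copy(), np.arange(40) * 100.0)
        assert first is None

    def test_constructed_divergence_located(self, rng):
        t = np.arange(-2000.0, 2000.0, 100.0)
        a = rng.standard_normal((20, t.size))
        b = rng.standard_normal((20, t.size))
        b[:, t >= -500.0] += 10.0
        first, p = timecourse_divergence(a, b, t)
        assert first is not None
        assert abs(first - (-500.0)) <= 100.0

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            timecourse_divergence(
                rng.standard_normal((5, 10)),
                rng.standard_normal((5, 12)),
                np.arange(10),
            )
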