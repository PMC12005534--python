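"""Generator contracts: determinism, condition structure, Poisson
statistics, report model, decoder-trace construction, LFP envelopes."""

import numpy as np
import pytest
from scipy import signal, stats

from intentchain.session_model import Condition, ExperimentConfig, ReportQuery, Trial
from intentchain.spiking_analysis import smooth_counts
from intentchain.synthetic_data import (
    GeneratorParams,
    UnitSpec,
    generate_decoder_trace,
    generate_lfp,
    generate_reports,
    generate_session,
    generate_session_with_truth,
    generate_spike_train,
)

TINY = dict(n_trials_per_condition=3, n_channels=4, n_sorted_units=3, lfp_channels=1)


def _intent_trial(t_action=5000.0, condition=Condition.IA, query=ReportQuery.INTENTION):
    return Trial(
        trial_id="t0",
        condition=condition,
        report_query=query,
        clock_phase_units=0.0,
        t_action_ms=t_action if condition.has_action else None,
        t_tone_ms=t_action + 300.0 if condition.has_effect else None,
        t_decoder_intent_ms=t_action - 70.0 if condition.has_intention else None,
    )


class TestSessionStructure:
    def test_determinism(self):
        p = GeneratorParams(**TINY)
        b1 = generate_session(p, seed=42)
        b2 = generate_session(p, seed=42)
        assert b1.trials == b2.trials
        for s1, s2 in zip(b1.spikes, b2.spikes):
            np.testing.assert_array_equal(s1.spike_times_ms, s2.spike_times_ms)
        for tid in b1.decoder_traces:
            np.testing.assert_array_equal(
                b1.decoder_traces[tid].values, b2.decoder_traces[tid].values
            )

    def test_zero_trials_valid(self):
        b = generate_session(GeneratorParams(n_trials_per_condition=0, **{
            k: v for k, v in TINY.items() if k != "n_trials_per_condition"}))
        assert b.trials == []
        b.validate()

    def test_condition_counts(self):
        b = generate_session(GeneratorParams(**TINY), seed=0)
        for cond in Condition:
            assert sum(t.condition is cond for t in b.trials) == 3

    def test_tone_delay_conserved(self, small_session):
        bundle, _ = small_session
        for t in bundle.trials:
            if t.t_action_ms is not None and t.t_tone_ms is not None:
                assert t.t_tone_ms - t.t_action_ms == pytest.approx(300.0)

    def test_queries_in_miniruns_of_five(self):
        p = GeneratorParams(n_trials_per_condition=10, n_channels=4, n_sorted_units=3,
                            lfp_channels=1)
        b = generate_session(p, seed=0)
        iae = [t for t in b.trials if t.condition is Condition.IAE]
        # first five share a query, next five share the following query
        assert len({t.report_query for t in iae[:5]}) == 1
        assert len({t.report_query for t in iae[5:10]}) == 1
        assert iae[0].report_query is not iae[5].report_query


class TestReports:
    def test_zero_bias_zero_noise_maps_to_event(self, config):
        p = GeneratorParams(
            action_bias_ms=0.0, action_sd_ms=1e-9, binding_action_ms=0.0, **TINY
        )
        trial = _intent_trial(condition=Condition.A_ONLY, query=ReportQuery.ACTION)
        rng = np.random.default_rng(0)
        rep = generate_reports(trial, p, rng, config)
        from intentchain.session_model import report_to_event_relative_time
        from dataclasses import replace

        t2 = replace(trial, report_units=rep)
        off = report_to_event_relative_time(t2, trial.t_action_ms, config)
        assert off == pytest.approx(0.0, abs=1e-3)

    def test_monte_carlo_bias_recovery(self, config):
        """Empirical median offset converges to the configured bias."""
        p = GeneratorParams(action_bias_ms=-455.0, action_sd_ms=100.0,
                            binding_action_ms=0.0, **TINY)
        rng = np.random.default_rng(9)
        trial = _intent_trial(condition=Condition.A_ONLY, query=ReportQuery.ACTION)
        from dataclasses import replace
        from intentchain.session_model import report_to_event_relative_time

        offs = []
        for _ in range(10_000):
            rep = generate_reports(trial, p, rng, config)
            offs.append(
                report_to_event_relative_time(
                    replace(trial, report_units=rep), trial.t_action_ms, config
                )
            )
        assert np.median(offs) == pytest.approx(-455.0, abs=5.0)


class TestSpikeTrains:
    def test_zero_rate_empty(self, rng):
        unit = UnitSpec("u", 1, True, baseline_hz=0.0)
        st = generate_spike_train(unit, _intent_trial(), rng)
        assert st.n_spikes == 0

    def test_constant_rate_poisson_statistics(self):
        """10 Hz for 100 s: count within 3 sigma, exponential ISIs."""
        unit = UnitSpec("u", 1, True, baseline_hz=10.0)
        trial = _intent_trial(condition=Condition.E_ONLY, query=ReportQuery.EFFECT)
        n_pass = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            st = generate_spike_train(unit, trial, rng, duration_ms=100_000.0)
            assert abs(st.n_spikes - 1000) < 3 * np.sqrt(1000)
            isis = np.diff(st.spike_times_ms)
            p = stats.kstest(isis, "expon", args=(0, isis.mean())).pvalue
            n_pass += p > 0.01
        assert n_pass >= 19  # >= 95% of seeds pass at alpha = 0.01

    def test_psth_recovers_step_profile(self):
        """Smoothed PSTH over many trials tracks the generating rate."""
        params = GeneratorParams(**TINY)
        unit = UnitSpec(
            "u", 1, True, baseline_hz=5.0, step_amp_hz=15.0, alpha_ms=20.0,
            t0_offset_ms=0.0, responsive=True,
        )
        trial = _intent_trial(condition=Condition.IA)
        params_nojit = GeneratorParams(step_t0_jitter_sd_ms=1e-9, **TINY)
        rng = np.random.default_rng(2)
        latent = 4500.0
        n_trials = 500
        counts = np.zeros((n_trials, 10_000))
        for i in range(n_trials):
            st = generate_spike_train(
                unit, trial, rng, params_nojit, latent_intent_ms=latent
            )
            idx = st.spike_times_ms.astype(int)
            np.add.at(counts[i], idx[idx < 10_000], 1.0)
        psth = smooth_counts(counts.mean(axis=0)[None, :], 50.0)[0]
        t = np.arange(10_000.0)
        true_rate = 5.0 + 15.0 / (1.0 + np.exp(-(t - latent) / 20.0))
        # compare away from edges; smoothing broadens the step slightly
        sel = (t > 1000) & (t < 9000) & (np.abs(t - latent) > 150)
        assert np.max(np.abs(psth[sel] - true_rate[sel])) < 1.5  # Hz

    def test_negative_bound_raises(self, rng):
        with pytest.raises(Exception):
            generate_spike_train(
                UnitSpec("u", 1, True, baseline_hz=-5.0), _intent_trial(), rng
            )


class TestDecoderTraces:
    def test_intended_crossing_exact(self, rng):
        p = GeneratorParams(**TINY)
        trial = _intent_trial(condition=Condition.IAE, query=ReportQuery.ACTION)
        tr = generate_decoder_trace(trial, p, rng)
        from intentchain.decoder_pipeline import threshold_crossing

        assert threshold_crossing(tr) == pytest.approx(trial.t_action_ms)

    def test_values_bounded(self, small_session):
        bundle, _ = small_session
        for tr in bundle.decoder_traces.values():
            assert tr.values.min() >= -1.0 and tr.values.max() <= 1.0

    def test_ensemble_ramp_onset_near_lead(self):
        """The mean intended trace exceeds rest noise by 5 SD-of-mean
        roughly lead_ms before the crossing (within one bin of the
        ramp's expected detection point)."""
        p = GeneratorParams(**TINY)
        trial = _intent_trial(condition=Condition.IAE, query=ReportQuery.ACTION)
        rng = np.random.default_rng(0)
        traces = np.vstack(
            [generate_decoder_trace(trial, p, rng).values for _ in range(200)]
        )
        mean = traces.mean(axis=0)
        t = np.arange(mean.size) * 100.0
        rest = t < trial.t_action_ms - p.decoder_lead_ms - 200.0
        mu, sd = mean[rest].mean(), mean[rest].std()
        above = np.flatnonzero(mean > mu + 5 * sd)
        onset = t[above[0]]
        # expected detection: ramp rises |rest|/lead per ms from ramp start
        expected = trial.t_action_ms - p.decoder_lead_ms + 5 * sd / (
            abs(p.decoder_rest_mean) / p.decoder_lead_ms
        )
        assert abs(onset - expected) <= 200.0  # within 2 bins

    def test_no_lead_no_premovement_divergence(self):
        """Ablation: with lead_ms=0 IAE and AE do not diverge before
        movement."""
        base = dict(TINY)
        trial_iae = _intent_trial(condition=Condition.IAE, query=ReportQuery.ACTION)
        trial_ae = Trial(
            trial_id="t1", condition=Condition.AE, report_query=ReportQuery.ACTION,
            clock_phase_units=0.0, t_action_ms=5000.0, t_tone_ms=5300.0,
        )
        for lead, expect_diverge in [(1100.0, True), (0.0, False)]:
            p = GeneratorParams(decoder_lead_ms=lead, decoder_abrupt_rise_ms=300.0,
                                decoder_rise_ms=300.0, **base)
            rng = np.random.default_rng(1)
            a = np.vstack([generate_decoder_trace(trial_iae, p, rng).values for _ in range(30)])
            b = np.vstack([generate_decoder_trace(trial_ae, p, rng).values for _ in range(30)])
            pre = slice(25, 49)  # 2500..4900 ms, strictly pre-movement
            tt = stats.ttest_ind(a[:, pre], b[:, pre], axis=0)
            if expect_diverge:
                assert (tt.pvalue < 0.01).any()
            else:
                assert not (tt.pvalue < 1e-4).any()


class TestLfp:
    def test_delta_power_rises_before_action_with_intention(self):
        p = GeneratorParams(**TINY)
        rng = np.random.default_rng(4)
        trial_i = _intent_trial(condition=Condition.IA)
        trial_n = Trial(
            trial_id="t1", condition=Condition.A_ONLY, report_query=ReportQuery.ACTION,
            clock_phase_units=0.0, t_action_ms=5000.0,
        )
        def delta_power_pre(trial, n=30):
            acc = 0.0
            for _ in range(n):
                tr = generate_lfp(trial, p, rng)
                f, t, sxx = signal.spectrogram(tr.values[0], fs=tr.fs_hz, nperseg=256)
                band = (f >= 0.5) & (f <= 4.0)
                pre = (t * 1000 >= 4200) & (t * 1000 < 4900)
                acc += sxx[band][:, pre].mean()
            return acc / n

        assert delta_power_pre(trial_i) > 1.5 * delta_power_pre(trial_n)

    def test_zero_envelopes_flat_band_power(self):
        p = GeneratorParams(lfp_delta_amp=0.0, lfp_alpha_amp=0.0, lfp_beta_amp=0.0, **TINY)
        rng = np.random.default_rng(8)
        tr = generate_lfp(_intent_trial(condition=Condition.IA), p, rng)
        f, t, sxx = signal.spectrogram(tr.values[0], fs=tr.fs_hz, nperseg=256)
        band = (f >= 0.5) & (f <= 4.0)
        bp = sxx[band].mean(axis=0)
        pre = bp[(t * 1000 < 4000)]
        post = bp[(t * 1000 >= 4000)]
        # no condition-locked structure: halves within a factor ~2
        assert 0.4 < pre.mean() / post.mean() < 2.5


class TestInjectedCorrelation:
    def test_correlated_units_hit_target(self):
        """Mean empirical corr(count, report) across correlated units is
        near the configured target at 50 trials/condition."""
        p = GeneratorParams(
            n_trials_per_condition=50, n_channels=4, n_sorted_units=25,
            frac_intent_correlated=0.4, include_lfp=False,
        )
        bundle, truth = generate_session_with_truth(p, seed=11)
        from intentchain.pipeline import pre_action_spike_counts

        counts, offsets, unit_ids = pre_action_spike_counts(bundle)
        corr_ids = {u.unit_id for u in truth["units"] if u.correlated}
        rs = []
        for c, uid in zip(counts, unit_ids):
            if uid in corr_ids and np.std(c) > 0:
                rs.append(stats.pearsonr(c, offsets).statistic)
        assert len(rs) >= 3
        # reading noise dilutes the latent-coupled target slightly
        assert np.mean(rs) == pytest.approx(p.target_corr, abs=0.15)
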