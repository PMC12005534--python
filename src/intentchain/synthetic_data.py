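"""Synthetic session generator.

Generates :class:`~intentchain.session_model.SessionBundle` objects with
the statistical structure the analyses assume, so every pipeline stage is
testable without any external data:

* six trial conditions (full chain IAE; AE; IE; IA; A-only; E-only) with
  50 repetitions each, report queries varied in mini-runs of 5 trials;
* Libet-clock reports with condition-dependent biases, decoder-quality-
  dependent binding shifts, and Gaussian report noise wrapped onto the
  clock;
* 96-channel multi-unit and >= 66 sorted-unit spike trains as
  inhomogeneous Poisson processes (thinning), combining a baseline, a
  logistic intention step locked to a *latent* subjective-intention time,
  and a Gaussian movement transient;
* per-trial decoder traces in [-1, 1] on 100 ms bins, crossing zero
  exactly at action with a slow ramp beginning ``lead_ms`` earlier on
  intended trials;
* per-trial LFP as 1/f noise plus band-limited oscillations whose
  envelopes follow the condition rules (sustained low-frequency power
  pre-movement only with intention; alpha/beta transient post-movement).

The subjective intention time is a latent variable per trial
(action + bias + noise); the clock report is a noisy reading of it, and
neural intention steps lock to the latent time, not to the report.  This
creates the report-alignment structure the spiking analyses exploit.

Each trial occupies a fixed slot of ``trial_slot_ms`` on the session
timeline; spike times are session-relative, all other per-trial times are
trial-relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from intentchain.session_model import (
    Condition,
    ContinuousTrace,
    ExperimentConfig,
    ReportQuery,
    SessionBundle,
    SpikeTrain,
    TraceKind,
    Trial,
    VALID_QUERIES,
    ValidationError,
    clock_position_at,
)

__all__ = [
    "GeneratorParams",
    "UnitSpec",
    "generate_session",
    "generate_session_with_truth",
    "generate_reports",
    "generate_spike_train",
    "generate_decoder_trace",
    "generate_lfp",
    "generate_raw_snippet",
    "generate_calibration_features",
    "trial_start_ms",
]

#: inter-trial slot length (ms); trial k occupies [k*slot, (k+1)*slot)
DEFAULT_TRIAL_SLOT_MS = 10_000.0


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic session generator.

    Report biases and dispersions default to the experiment's values:
    intention -597 ms, action -455 ms, effect -512 ms, with per-trial
    SDs equal to the reported standard errors (37.2 / 21.4 / 17.2 ms at
    n = 50) scaled by sqrt(50).
    """

    n_trials_per_condition: int = 50
    n_channels: int = 96
    n_sorted_units: int = 66

    # trial timing (ms, trial-relative); action snapped to the decoder grid
    trial_slot_ms: float = DEFAULT_TRIAL_SLOT_MS
    t_action_min_ms: float = 4000.0
    t_action_max_ms: float = 6000.0

    # spiking
    baseline_rate_mean_hz: float = 5.0
    baseline_rate_shape: float = 2.0
    mua_baseline_mean_hz: float = 12.0
    intent_step_amp_mean_hz: float = 10.0
    mua_step_amp_mean_hz: float = 6.0
    step_t0_offset_ms: float = -108.0
    step_t0_jitter_sd_ms: float = 50.0
    step_alpha_mean_ms: float = 23.0
    transient_amp_mean_hz: float = 15.0
    mua_transient_amp_mean_hz: float = 20.0
    transient_latency_ms: float = 373.0
    transient_width_ms: float = 150.0
    frac_intent_responsive: float = 0.3
    frac_intent_correlated: float = 0.12
    target_corr: float = 0.5

    # clock reports (ms)
    intention_bias_ms: float = -597.0
    action_bias_ms: float = -455.0
    effect_bias_ms: float = -512.0
    intention_sd_ms: float = 37.2 * math.sqrt(50)
    action_sd_ms: float = 21.4 * math.sqrt(50)
    effect_sd_ms: float = 17.2 * math.sqrt(50)
    #: share of intention-report variance carried by the latent time
    latent_variance_frac: float = 0.9
    #: binding shifts per unit decoder quality (intention later, action
    #: earlier on high-quality trials)
    binding_intention_ms: float = 80.0
    binding_action_ms: float = -50.0

    # decoder traces
    decoder_rest_mean: float = -0.6
    decoder_noise_sd: float = 0.05
    decoder_lead_ms: float = 1100.0
    decoder_peak: float = 0.75
    decoder_peak_q_gain: float = 0.08
    decoder_rise_ms: float = 300.0
    decoder_abrupt_rise_ms: float = 200.0
    decoder_decay_ms: float = 500.0
    decoder_hold_iae_ms: float = 800.0
    decoder_hold_ia_ms: float = 1500.0
    decoder_hold_ie_ms: float = 100.0

    # LFP
    lfp_fs_hz: float = 500.0
    lfp_channels: int = 3
    lfp_noise_sd: float = 1.0
    lfp_delta_hz: float = 2.0
    lfp_delta_amp: float = 1.5
    lfp_delta_lead_ms: float = 1000.0
    lfp_alpha_hz: float = 10.0
    lfp_alpha_amp: float = 1.0
    lfp_beta_hz: float = 20.0
    lfp_beta_amp: float = 0.8
    lfp_transient_ms: float = 500.0

    include_lfp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_intent_responsive", "frac_intent_correlated", "latent_variance_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in (
            "baseline_rate_mean_hz",
            "intent_step_amp_mean_hz",
            "transient_amp_mean_hz",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.step_alpha_mean_ms <= 0:
            raise ValidationError("step_alpha_mean_ms must be > 0")
        for name in ("intention_sd_ms", "action_sd_ms", "effect_sd_ms", "decoder_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_trials_per_condition < 0:
            raise ValidationError("n_trials_per_condition must be >= 0")
        if abs(self.target_corr) >= 1:
            raise ValidationError("target_corr must be in (-1, 1)")

    def bias_ms(self, query: ReportQuery) -> float:
        return {
            ReportQuery.INTENTION: self.intention_bias_ms,
            ReportQuery.ACTION: self.action_bias_ms,
            ReportQuery.EFFECT: self.effect_bias_ms,
        }[query]

    def sd_ms(self, query: ReportQuery) -> float:
        return {
            ReportQuery.INTENTION: self.intention_sd_ms,
            ReportQuery.ACTION: self.action_sd_ms,
            ReportQuery.EFFECT: self.effect_sd_ms,
        }[query]

    def to_config(self) -> ExperimentConfig:
        return ExperimentConfig(rng_seed=self.seed)


@dataclass(frozen=True)
class UnitSpec:
    """Per-unit generative parameters for spike-train synthesis."""

    unit_id: str
    channel: int
    is_sorted_unit: bool
    baseline_hz: float
    step_amp_hz: float = 0.0
    alpha_ms: float = 23.0
    t0_offset_ms: float = -108.0
    transient_amp_hz: float = 0.0
    responsive: bool = False
    correlated: bool = False
    corr_gain: float = 0.0


def trial_start_ms(bundle: SessionBundle, trial: Trial, slot_ms: float = DEFAULT_TRIAL_SLOT_MS) -> float:
    """Session-timeline start of a trial's slot (trials occupy uniform slots)."""
    idx = [t.trial_id for t in bundle.trials].index(trial.trial_id)
    return idx * slot_ms


# ---------------------------------------------------------------------------
# reports


def _wrap_report(t_report_ms: float, phase_units: float, config: ExperimentConfig) -> float:
    return clock_position_at(t_report_ms, phase_units, config)


#: largest |event-relative offset| a generated report may carry, as a
#: fraction of the clock cycle.  Subjective reports cluster well within
#: one second of their event; bounding the noise keeps the
#: nearest-occurrence unwrapping bijective (no report ever refers to the
#: far side of the cycle).
_MAX_OFFSET_FRAC = 0.45


def _bounded_shift(
    mean_ms: float, sd_ms: float, rng: np.random.Generator, config: ExperimentConfig
) -> float:
    """mean + truncated-normal noise, kept within the representable
    half-cycle around the event."""
    lim = _MAX_OFFSET_FRAC * config.clock_cycle_ms
    for _ in range(100):
        shift = mean_ms + rng.normal(0.0, sd_ms)
        if abs(shift) < lim:
            return shift
    return float(np.clip(shift, -lim, lim))


def generate_reports(
    trial: Trial,
    params: GeneratorParams,
    rng: np.random.Generator,
    config: Optional[ExperimentConfig] = None,
    quality: float = 0.0,
    latent_intent_ms: Optional[float] = None,
) -> float:
    """Draw a clock report (units) for a trial's query.

    Report time = event + bias(query) + binding shift (scaled by the
    trial's decoder quality ``quality``) + Gaussian noise, wrapped onto
    the clock at the trial's phase.  For intention queries the latent
    subjective-intention time may be passed in; otherwise it is drawn
    here.
    """
    config = config or params.to_config()
    query = trial.report_query
    if query is ReportQuery.NONE:
        raise ValidationError(f"trial {trial.trial_id}: no report queried")
    ref_action = trial.t_action_ms
    if ref_action is None and trial.t_tone_ms is not None:
        ref_action = trial.t_tone_ms - config.tone_delay_ms
    if query is ReportQuery.EFFECT:
        if trial.t_tone_ms is None:
            raise ValidationError(f"trial {trial.trial_id}: no tone to report")
        t_report = trial.t_tone_ms + _bounded_shift(
            params.effect_bias_ms, params.effect_sd_ms, rng, config
        )
    elif query is ReportQuery.ACTION:
        if ref_action is None:
            raise ValidationError(f"trial {trial.trial_id}: no action to report")
        t_report = ref_action + _bounded_shift(
            params.action_bias_ms + params.binding_action_ms * quality,
            params.action_sd_ms,
            rng,
            config,
        )
    else:  # INTENTION: noisy reading of the latent time
        if ref_action is None:
            raise ValidationError(f"trial {trial.trial_id}: no action reference")
        if latent_intent_ms is None:
            latent_intent_ms = _draw_latent_intent(ref_action, params, rng, quality, config)
        read_sd = params.intention_sd_ms * math.sqrt(1.0 - params.latent_variance_frac)
        t_report = ref_action + _bounded_shift(
            latent_intent_ms - ref_action, read_sd, rng, config
        )
    return _wrap_report(t_report, trial.clock_phase_units, config)


def _draw_latent_intent(
    t_action_ms: float,
    params: GeneratorParams,
    rng: np.random.Generator,
    quality: float,
    config: Optional[ExperimentConfig] = None,
) -> float:
    config = config or params.to_config()
    latent_sd = params.intention_sd_ms * math.sqrt(params.latent_variance_frac)
    return t_action_ms + _bounded_shift(
        params.intention_bias_ms + params.binding_intention_ms * quality,
        latent_sd,
        rng,
        config,
    )


# ---------------------------------------------------------------------------
# spikes


def _rate_profile(
    t_ms: np.ndarray,
    unit: UnitSpec,
    trial: Trial,
    latent_intent_ms: Optional[float],
    corr_z: float,
    t0_jitter_ms: float,
    params: GeneratorParams,
) -> np.ndarray:
    """Instantaneous rate (Hz) of a unit at trial-relative times ``t_ms``."""
    rate = np.full_like(t_ms, unit.baseline_hz, dtype=float)
    has_intent = trial.condition.has_intention and latent_intent_ms is not None
    if unit.responsive and unit.step_amp_hz > 0 and has_intent:
        t0 = latent_intent_ms + unit.t0_offset_ms + t0_jitter_ms
        rate += unit.step_amp_hz * expit((t_ms - t0) / unit.alpha_ms)
    if unit.transient_amp_hz > 0 and trial.t_action_ms is not None:
        peak_t = trial.t_action_ms + params.transient_latency_ms
        rate += unit.transient_amp_hz * np.exp(
            -0.5 * ((t_ms - peak_t) / params.transient_width_ms) ** 2
        )
    ref_action = trial.t_action_ms
    if ref_action is None and trial.t_tone_ms is not None:
        ref_action = trial.t_tone_ms - 300.0
    if unit.correlated and ref_action is not None:
        in_win = (t_ms >= ref_action - 1000.0) & (t_ms < ref_action)
        rate[in_win] += unit.baseline_hz * unit.corr_gain * corr_z
    return np.maximum(rate, 0.0)


def generate_spike_train(
    unit: UnitSpec,
    trial: Trial,
    rng: np.random.Generator,
    params: Optional[GeneratorParams] = None,
    latent_intent_ms: Optional[float] = None,
    corr_z: float = 0.0,
    duration_ms: Optional[float] = None,
) -> SpikeTrain:
    """Realize one trial of a unit as an inhomogeneous Poisson process.

    Uses thinning: homogeneous candidates at the rate-profile maximum are
    accepted with probability rate(t)/max.  Times are trial-relative.
    """
    params = params or GeneratorParams()
    duration_ms = duration_ms if duration_ms is not None else params.trial_slot_ms
    t0_jitter = rng.normal(0.0, params.step_t0_jitter_sd_ms) if unit.responsive else 0.0
    rate_max = (
        unit.baseline_hz * (1.0 + abs(unit.corr_gain * corr_z))
        + unit.step_amp_hz
        + unit.transient_amp_hz
    )
    if rate_max < 0:
        raise ValidationError("negative rate bound")
    if rate_max == 0:
        return SpikeTrain(unit.unit_id, unit.channel, np.array([]), unit.is_sorted_unit)
    n_cand = rng.poisson(rate_max * duration_ms / 1000.0)
    cand = np.sort(rng.uniform(0.0, duration_ms, size=n_cand))
    if n_cand == 0:
        return SpikeTrain(unit.unit_id, unit.channel, np.array([]), unit.is_sorted_unit)
    rate = _rate_profile(cand, unit, trial, latent_intent_ms, corr_z, t0_jitter, params)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate / rate_max
    return SpikeTrain(unit.unit_id, unit.channel, cand[keep], unit.is_sorted_unit)


# ---------------------------------------------------------------------------
# decoder traces


def generate_decoder_trace(
    trial: Trial,
    params: GeneratorParams,
    rng: np.random.Generator,
    config: Optional[ExperimentConfig] = None,
    quality: float = 0.0,
) -> ContinuousTrace:
    """Per-trial decoder output on 100 ms bins, clipped to [-1, 1].

    Intended trials (I present) ramp from rest beginning ``lead_ms``
    before threshold and cross zero exactly at the action bin; AE/A-only
    (NMES) trials rise abruptly at movement; IE trials plummet shortly
    after crossing; IA trials hold their plateau longer (no effect).
    The zero-crossing bin is noise-free and pre-crossing bins are kept
    strictly negative so the crossing time is exact by construction.
    """
    config = config or params.to_config()
    bin_ms = config.decoder_bin_ms
    n_bins = int(round(params.trial_slot_ms / bin_ms))
    t = np.arange(n_bins) * bin_ms
    rest = params.decoder_rest_mean
    shape = np.full(n_bins, rest)

    cond = trial.condition
    t_cross = trial.t_action_ms
    if t_cross is None and trial.t_tone_ms is not None:
        t_cross = trial.t_tone_ms - config.tone_delay_ms
    peak = float(np.clip(params.decoder_peak + params.decoder_peak_q_gain * quality, 0.3, 0.98))

    if cond.has_intention and t_cross is not None:
        ramp_start = t_cross - params.decoder_lead_ms
        in_ramp = (t >= ramp_start) & (t < t_cross)
        shape[in_ramp] = rest * (t_cross - t[in_ramp]) / params.decoder_lead_ms
        hold = {
            Condition.IAE: params.decoder_hold_iae_ms,
            Condition.IA: params.decoder_hold_ia_ms,
            Condition.IE: params.decoder_hold_ie_ms,
        }[cond]
        shape = _post_cross(shape, t, t_cross, peak, params.decoder_rise_ms, hold,
                            params.decoder_decay_ms, rest)
    elif cond.has_action and t_cross is not None:  # AE / A_ONLY: abrupt rise at movement
        shape = _post_cross(shape, t, t_cross, peak, params.decoder_abrupt_rise_ms,
                            params.decoder_hold_iae_ms, params.decoder_decay_ms, rest)
    # E_ONLY: rest throughout

    values = shape + rng.normal(0.0, params.decoder_noise_sd, size=n_bins)
    if t_cross is not None and cond.has_action or (cond is Condition.IE and t_cross is not None):
        k = int(t_cross // bin_ms)
        if 0 <= k < n_bins:
            pre = slice(0, k)
            values[pre] = np.minimum(values[pre], -0.02)
            values[k] = shape[k] if shape[k] >= 0 else 0.0
    return ContinuousTrace(
        kind=TraceKind.DECODER,
        fs_hz=1000.0 / bin_ms,
        t0_ms=0.0,
        values=np.clip(values, -1.0, 1.0),
    )


def _post_cross(shape, t, t_cross, peak, rise_ms, hold_ms, decay_ms, rest):
    rise = (t >= t_cross) & (t < t_cross + rise_ms)
    shape[rise] = peak * (t[rise] - t_cross) / rise_ms
    plateau = (t >= t_cross + rise_ms) & (t < t_cross + rise_ms + hold_ms)
    shape[plateau] = peak
    decay_start = t_cross + rise_ms + hold_ms
    dec = (t >= decay_start) & (t < decay_start + decay_ms)
    shape[dec] = peak + (rest - peak) * (t[dec] - decay_start) / decay_ms
    shape[t >= decay_start + decay_ms] = rest
    return shape


# ---------------------------------------------------------------------------
# LFP


def _pink_noise(n: int, rng: np.random.Generator, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x *= sd / x.std()
    return x


def _envelope(t: np.ndarray, on_ms: float, off_ms: float, ramp_ms: float = 100.0) -> np.ndarray:
    env = np.clip((t - on_ms) / ramp_ms, 0.0, 1.0) * np.clip((off_ms - t) / ramp_ms, 0.0, 1.0)
    return np.clip(env, 0.0, 1.0)


def generate_lfp(
    trial: Trial,
    params: GeneratorParams,
    rng: np.random.Generator,
    config: Optional[ExperimentConfig] = None,
) -> ContinuousTrace:
    """Per-trial multi-channel LFP: 1/f background + band oscillations.

    Delta (and weaker theta) power is sustained from ``lfp_delta_lead_ms``
    before the action only when intention is present; when movement is
    provoked without intention the low-frequency envelope switches on
    only after movement.  Alpha/beta bursts follow movement.
    """
    config = config or params.to_config()
    fs = params.lfp_fs_hz
    n = int(round(params.trial_slot_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    t_act = trial.t_action_ms
    if t_act is None and trial.t_tone_ms is not None:
        t_act = trial.t_tone_ms - config.tone_delay_ms

    chans = []
    for _ in range(params.lfp_channels):
        x = _pink_noise(n, rng, params.lfp_noise_sd)
        if t_act is not None:
            if trial.condition.has_intention:
                delta_env = _envelope(t, t_act - params.lfp_delta_lead_ms,
                                      t_act + params.lfp_transient_ms)
            else:
                delta_env = _envelope(t, t_act, t_act + params.lfp_transient_ms)
            ph = rng.uniform(0, 2 * np.pi)
            x += params.lfp_delta_amp * delta_env * np.sin(
                2 * np.pi * params.lfp_delta_hz * t / 1000.0 + ph
            )
            if trial.condition.has_action:
                move_env = _envelope(t, t_act, t_act + params.lfp_transient_ms)
                x += params.lfp_alpha_amp * move_env * np.sin(
                    2 * np.pi * params.lfp_alpha_hz * t / 1000.0 + rng.uniform(0, 2 * np.pi)
                )
                x += params.lfp_beta_amp * move_env * np.sin(
                    2 * np.pi * params.lfp_beta_hz * t / 1000.0 + rng.uniform(0, 2 * np.pi)
                )
        chans.append(x)
    return ContinuousTrace(kind=TraceKind.LFP, fs_hz=fs, t0_ms=0.0, values=np.vstack(chans))


# ---------------------------------------------------------------------------
# raw snippets & calibration features


def generate_raw_snippet(
    duration_ms: float,
    n_channels: int,
    rng: np.random.Generator,
    fs_hz: float = 30000.0,
    burst_times_ms: Optional[np.ndarray] = None,
    burst_amp_uv: float = 60.0,
    artifact_times_ms: Optional[np.ndarray] = None,
    artifact_amp_uv: float = 600.0,
    artifact_channels: Optional[np.ndarray] = None,
    noise_sd_uv: float = 10.0,
) -> ContinuousTrace:
    """Raw-rate (30 kHz) snippet: band-limited noise with optional
    multi-unit energy bursts (235 Hz-3.75 kHz) and NMES-like artifacts.

    Artifacts are square deflections of ``artifact_amp_uv`` lasting 1 ms
    on ``artifact_channels`` (all channels if None).
    """
    from scipy.signal import butter, sosfiltfilt

    n = int(round(duration_ms * fs_hz / 1000.0))
    x = rng.standard_normal((n_channels, n)) * noise_sd_uv
    if burst_times_ms is not None and len(burst_times_ms):
        sos = butter(4, [235.0, 3750.0], btype="bandpass", fs=fs_hz, output="sos")
        carrier = sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= max(carrier.std(), 1e-12)
        t = np.arange(n) * 1000.0 / fs_hz
        env = np.zeros(n)
        for bt in np.atleast_1d(burst_times_ms):
            env += np.exp(-0.5 * ((t - bt) / 5.0) ** 2)
        x += burst_amp_uv * carrier * env
    if artifact_times_ms is not None:
        ch = (
            np.arange(n_channels)
            if artifact_channels is None
            else np.asarray(artifact_channels, dtype=int)
        )
        w = int(fs_hz / 1000.0)  # 1 ms square pulse
        for at in np.atleast_1d(artifact_times_ms):
            i0 = int(at * fs_hz / 1000.0)
            x[np.ix_(ch, range(i0, min(i0 + w, n)))] += artifact_amp_uv
    return ContinuousTrace(kind=TraceKind.RAW, fs_hz=fs_hz, t0_ms=0.0, values=x)


def generate_calibration_features(
    rng: np.random.Generator,
    n_blocks: int = 7,
    reps_per_movement: int = 5,
    n_features: int = 96,
    n_rest_per_block: int = 10,
    class_sep: float = 2.0,
    frac_informative: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic MWP feature set replicating the calibration protocol
    (7 blocks x 5 repetitions per hand movement, plus rest bins).

    Returns (X, y) with y in {'rest', 'HC', 'HO'}; class means differ on
    a random informative subset of channels.
    """
    n_inf = max(1, int(frac_informative * n_features))
    idx = rng.permutation(n_features)
    hc_idx, ho_idx = idx[:n_inf], idx[n_inf : 2 * n_inf]
    X_rows, y_rows = [], []
    for _ in range(n_blocks):
        for label, chans in (("HC", hc_idx), ("HO", ho_idx)):
            for _ in range(reps_per_movement):
                v = rng.standard_normal(n_features)
                v[chans] += class_sep
                X_rows.append(v)
                y_rows.append(label)
        for _ in range(n_rest_per_block):
            X_rows.append(rng.standard_normal(n_features))
            y_rows.append("rest")
    return np.asarray(X_rows), np.asarray(y_rows)


# ---------------------------------------------------------------------------
# full session


def _draw_units(params: GeneratorParams, rng: np.random.Generator) -> list[UnitSpec]:
    units: list[UnitSpec] = []
    scale = params.baseline_rate_mean_hz / params.baseline_rate_shape
    # responsive and report-correlated populations are disjoint: a unit
    # carrying the intention step in the count window would otherwise
    # confound the injected rate-gain coupling
    u = rng.uniform(0, 1, params.n_sorted_units)
    k_resp = u < params.frac_intent_responsive
    k_corr = (u >= params.frac_intent_responsive) & (
        u < params.frac_intent_responsive + params.frac_intent_correlated
    )
    for i in range(params.n_sorted_units):
        b = rng.gamma(params.baseline_rate_shape, scale)
        b = max(b, 0.5)
        lam = b * 1.0  # expected count in the 1 s correlation window
        r = params.target_corr
        gain = r / math.sqrt(lam * (1 - r**2)) / 1.0 if k_corr[i] else 0.0
        units.append(
            UnitSpec(
                unit_id=f"unit{i:03d}",
                channel=int(rng.integers(1, params.n_channels + 1)),
                is_sorted_unit=True,
                baseline_hz=b,
                step_amp_hz=rng.gamma(4.0, params.intent_step_amp_mean_hz / 4.0)
                if k_resp[i]
                else 0.0,
                alpha_ms=max(rng.gamma(4.0, params.step_alpha_mean_ms / 4.0), 2.0),
                t0_offset_ms=params.step_t0_offset_ms,
                transient_amp_hz=rng.gamma(4.0, params.transient_amp_mean_hz / 4.0),
                responsive=bool(k_resp[i]),
                correlated=bool(k_corr[i]),
                corr_gain=gain,
            )
        )
    for c in range(1, params.n_channels + 1):
        units.append(
            UnitSpec(
                unit_id=f"ch{c:02d}",
                channel=c,
                is_sorted_unit=False,
                baseline_hz=max(rng.gamma(3.0, params.mua_baseline_mean_hz / 3.0), 1.0),
                step_amp_hz=rng.gamma(4.0, params.mua_step_amp_mean_hz / 4.0),
                alpha_ms=max(rng.gamma(4.0, params.step_alpha_mean_ms / 4.0), 2.0),
                t0_offset_ms=params.step_t0_offset_ms,
                transient_amp_hz=rng.gamma(4.0, params.mua_transient_amp_mean_hz / 4.0),
                responsive=True,  # channel-level MUA carries the population step
                correlated=False,
            )
        )
    return units


def _build_trials(
    params: GeneratorParams, config: ExperimentConfig, rng: np.random.Generator
) -> list[Trial]:
    bin_ms = config.decoder_bin_ms
    trials: list[Trial] = []
    idx = 0
    for cond in Condition:
        queries = VALID_QUERIES[cond]
        for k in range(params.n_trials_per_condition):
            query = queries[(k // 5) % len(queries)]  # mini-runs of 5
            t_action = rng.uniform(params.t_action_min_ms, params.t_action_max_ms)
            t_action = round(t_action / bin_ms) * bin_ms
            has_a = cond.has_action
            has_e = cond.has_effect
            has_i = cond.has_intention
            t_act_field = t_action if has_a and cond is not Condition.IE else None
            t_tone = t_action + config.tone_delay_ms if has_e else None
            # decoder-detectable intent precedes threshold by ~70 ms
            t_intent = t_action - 70.0 if has_i else None
            trials.append(
                Trial(
                    trial_id=f"t{idx:04d}",
                    condition=cond,
                    report_query=query,
                    clock_phase_units=float(rng.uniform(0, config.clock_units)),
                    t_action_ms=t_act_field,
                    t_tone_ms=t_tone,
                    t_decoder_intent_ms=t_intent,
                    report_units=None,
                )
            )
            idx += 1
    return trials


def generate_session_with_truth(
    params: Optional[GeneratorParams] = None, seed: Optional[int] = None
) -> tuple[SessionBundle, dict]:
    """Generate a full synthetic session plus its latent ground truth.

    Returns ``(bundle, truth)`` where ``truth`` holds per-trial latent
    intention times, decoder-quality draws, and the unit table — the
    quantities recovery tests compare against.
    """
    params = params or GeneratorParams()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    config = ExperimentConfig(rng_seed=seed)

    units = _draw_units(params, rng)
    trials = _build_trials(params, config, rng)

    latent: dict[str, Optional[float]] = {}
    quality: dict[str, float] = {}
    corr_z: dict[str, float] = {}
    filled: list[Trial] = []
    for tr in trials:
        q = float(rng.standard_normal())
        quality[tr.trial_id] = q
        ref_action = tr.t_action_ms
        if ref_action is None and tr.t_tone_ms is not None:
            ref_action = tr.t_tone_ms - config.tone_delay_ms
        li = None
        z = 0.0
        if tr.condition.has_intention and ref_action is not None:
            li = _draw_latent_intent(ref_action, params, rng, q, config)
            latent_sd = params.intention_sd_ms * math.sqrt(params.latent_variance_frac)
            z = (li - ref_action - params.intention_bias_ms - params.binding_intention_ms * q) / latent_sd
        latent[tr.trial_id] = li
        corr_z[tr.trial_id] = z
        report = generate_reports(tr, params, rng, config, quality=q, latent_intent_ms=li)
        filled.append(replace(tr, report_units=float(report)))
    trials = filled

    spikes: list[SpikeTrain] = []
    slot = params.trial_slot_ms
    for unit in units:
        all_times = []
        for k, tr in enumerate(trials):
            st = generate_spike_train(
                unit,
                tr,
                rng,
                params,
                latent_intent_ms=latent[tr.trial_id],
                corr_z=corr_z[tr.trial_id],
            )
            all_times.append(st.spike_times_ms + k * slot)
        spikes.append(
            SpikeTrain(
                unit.unit_id,
                unit.channel,
                np.concatenate(all_times) if all_times else np.array([]),
                unit.is_sorted_unit,
            )
        )

    decoder_traces = {
        tr.trial_id: generate_decoder_trace(tr, params, rng, config, quality[tr.trial_id])
        for tr in trials
    }
    lfp = (
        {tr.trial_id: generate_lfp(tr, params, rng, config) for tr in trials}
        if params.include_lfp
        else {}
    )

    bundle = SessionBundle(
        config=config,
        trials=trials,
        spikes=spikes,
        decoder_traces=decoder_traces,
        lfp=lfp,
    )
    bundle.validate()
    truth = {
        "latent_intent_ms": latent,
        "quality": quality,
        "corr_z": corr_z,
        "units": units,
        "params": params,
    }
    return bundle, truth


def generate_session(
    params: Optional[GeneratorParams] = None, seed: Optional[int] = None
) -> SessionBundle:
    """Generate a synthetic session; deterministic given (params, seed)."""
    bundle, _ = generate_session_with_truth(params, seed)
    return bundle
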