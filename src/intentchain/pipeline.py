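"""Session-level convenience analyses used by the CLI and scripts.

These functions glue the per-module operations to the session-bundle
layout: slicing session-timeline spike trains into trial slots, aligning
to objective or subjective (reported) event times, and assembling tidy
tables.  All heavy lifting lives in the analysis modules.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from intentchain.decoder_pipeline import (
    decoder_auc,
    estimate_rest_noise,
    objective_intention_time,
    threshold_crossing,
)
from intentchain.session_model import (
    Condition,
    ReportQuery,
    SessionBundle,
    read_session_bundle,
    reference_event_time,
    report_to_event_relative_time,
)
from intentchain.spiking_analysis import (
    MuaAverage,
    SigmoidFit,
    align_and_average,
    bin_session_spikes,
    evoked_onset,
    fit_sigmoid,
    smooth_counts,
)

DEFAULT_SLOT_MS = 10_000.0

__all__ = [
    "load_bundle",
    "action_reference_times",
    "report_times",
    "population_count_matrix",
    "condition_mua",
    "mua_summary",
    "channel_rate_stack",
    "intention_distance_curve",
    "decoder_trial_table",
    "trials_with_auc",
    "fit_session_sigmoids",
    "pre_action_spike_counts",
]


def load_bundle(bundle_or_path) -> SessionBundle:
    if isinstance(bundle_or_path, SessionBundle):
        return bundle_or_path
    return read_session_bundle(Path(bundle_or_path))


def action_reference_times(bundle: SessionBundle) -> np.ndarray:
    """Per-trial action (or would-have-moved) time; nan when undefined."""
    cfg = bundle.config
    out = np.full(len(bundle.trials), np.nan)
    for i, t in enumerate(bundle.trials):
        try:
            out[i] = reference_event_time(t, ReportQuery.ACTION, cfg)
        except Exception:
            pass
    return out


def report_times(bundle: SessionBundle, query: ReportQuery) -> np.ndarray:
    """Per-trial subjective (reported) event time, trial-relative; nan
    for trials without that report."""
    cfg = bundle.config
    out = np.full(len(bundle.trials), np.nan)
    for i, t in enumerate(bundle.trials):
        if t.report_query is not query or t.report_units is None:
            continue
        event = reference_event_time(t, query, cfg)
        out[i] = event + report_to_event_relative_time(t, event, cfg)
    return out


def population_count_matrix(
    bundle: SessionBundle,
    slot_ms: float = DEFAULT_SLOT_MS,
    bin_ms: float = 1.0,
    sorted_units: bool = False,
) -> np.ndarray:
    """Mean per-channel (or per-unit) spike counts, (n_trials, T).

    Sums binned counts over all multi-unit channels (or sorted units)
    and divides by their number — the population-average MUA.
    """
    n_trials = len(bundle.trials)
    n_bins = int(round(slot_ms / bin_ms))
    acc = np.zeros((n_trials, n_bins))
    n = 0
    for st in bundle.spikes:
        if st.is_sorted_unit != sorted_units:
            continue
        acc += bin_session_spikes(st, n_trials, slot_ms, bin_ms)
        n += 1
    if n == 0:
        raise ValueError("no spike trains of the requested kind")
    return acc / n


def condition_mua(
    bundle: SessionBundle,
    conditions: Sequence[Condition],
    align: str = "action",
    query: ReportQuery = ReportQuery.INTENTION,
    window: tuple[float, float] = (-2000.0, 2000.0),
    slot_ms: float = DEFAULT_SLOT_MS,
    counts: Optional[np.ndarray] = None,
) -> MuaAverage:
    """Aligned, trial-averaged population MUA for a set of conditions.

    ``align`` is "action" (objective movement time or its no-movement
    proxy), "report" (the subjective time of ``query``), or "tone".
    """
    counts = population_count_matrix(bundle, slot_ms) if counts is None else counts
    if align == "action":
        events = action_reference_times(bundle)
        mask = np.array([t.condition in conditions for t in bundle.trials])
    elif align == "report":
        events = report_times(bundle, query)
        mask = np.array(
            [t.condition in conditions and t.report_query is query for t in bundle.trials]
        )
    elif align == "tone":
        events = np.array(
            [t.t_tone_ms if t.t_tone_ms is not None else np.nan for t in bundle.trials]
        )
        mask = np.array([t.condition in conditions for t in bundle.trials])
    else:
        raise ValueError(f"unknown alignment {align!r}")
    mask &= np.isfinite(events)
    rates = smooth_counts(counts[mask], bundle.config.smoothing_sd_ms)
    return align_and_average(rates, events[mask], window, alignment=align)


def mua_summary(bundle_or_path, slot_ms: float = DEFAULT_SLOT_MS) -> pd.DataFrame:
    """Evoked-onset table: per condition group, movement-aligned MUA onset."""
    bundle = load_bundle(bundle_or_path)
    counts = population_count_matrix(bundle, slot_ms)
    rows = []
    groups = {
        "intention_only": [Condition.IE],
        "movement_no_intent": [Condition.AE, Condition.A_ONLY],
        "full_chain": [Condition.IAE],
    }
    for name, conds in groups.items():
        try:
            mua = condition_mua(bundle, conds, align="action", slot_ms=slot_ms, counts=counts)
            onset = evoked_onset(mua, k=bundle.config.onset_k)
            peak_t = float(mua.t_ms[np.argmax(mua.mean_rate_hz)])
            rows.append(
                {
                    "group": name,
                    "n_trials": mua.n_trials,
                    "onset_ms": onset,
                    "peak_time_ms": peak_t,
                    "peak_rate_hz": float(mua.mean_rate_hz.max()),
                }
            )
        except ValueError:
            continue
    return pd.DataFrame(rows)


def channel_rate_stack(
    bundle: SessionBundle,
    conditions: Sequence[Condition],
    window: tuple[float, float] = (-2000.0, 2000.0),
    bin_ms: float = 20.0,
    slot_ms: float = DEFAULT_SLOT_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial, per-channel aligned rate stack for population analyses.

    Returns ``(stack, t)`` with stack of shape (n_trials, n_channels,
    n_bins) on ``bin_ms`` resolution, smoothed with the session kernel.
    """
    events = action_reference_times(bundle)
    mask = np.array([t.condition in conditions for t in bundle.trials]) & np.isfinite(events)
    idx = np.flatnonzero(mask)
    n_trials = len(bundle.trials)
    w0, w1 = window
    n_out = int(round((w1 - w0) / bin_ms))
    chans = [st for st in bundle.spikes if not st.is_sorted_unit]
    stack = np.zeros((idx.size, len(chans), n_out))
    for c, st in enumerate(chans):
        counts = bin_session_spikes(st, n_trials, slot_ms, bin_ms)
        rates = smooth_counts(counts, bundle.config.smoothing_sd_ms, bin_ms)
        for j, i in enumerate(idx):
            b0 = int(round((events[i] + w0) / bin_ms))
            stack[j, c] = rates[i, b0 : b0 + n_out]
    t = w0 + np.arange(n_out) * bin_ms
    return stack, t


def intention_distance_curve(
    bundle_or_path, n_boot: int = 1000, seed: int = 0, bin_ms: float = 20.0
):
    """Bootstrap PCA distance between intention-present (IAE) and
    intention-absent (AE) movement trials, plus the PCA variance share."""
    from intentchain.population_analysis import bootstrap_distance, condition_pca

    bundle = load_bundle(bundle_or_path)
    a, t = channel_rate_stack(bundle, [Condition.IAE], bin_ms=bin_ms)
    b, _ = channel_rate_stack(bundle, [Condition.AE], bin_ms=bin_ms)
    _, var = condition_pca(
        {"IAE": a.mean(axis=0), "AE": b.mean(axis=0)}
    )
    curve = bootstrap_distance(a, b, t, n_boot=n_boot, rng=np.random.default_rng(seed))
    return curve, var


def decoder_trial_table(bundle_or_path) -> pd.DataFrame:
    """Per-trial decoder measures: crossing, objective intent time, AUC."""
    bundle = load_bundle(bundle_or_path)
    cfg = bundle.config
    noise_mean, noise_sd = estimate_rest_noise(list(bundle.decoder_traces.values()))
    events = action_reference_times(bundle)
    rows = []
    for i, t in enumerate(bundle.trials):
        tr = bundle.decoder_traces.get(t.trial_id)
        if tr is None:
            continue
        cross = threshold_crossing(tr)
        oit = objective_intention_time(tr, noise_mean, noise_sd, k=cfg.onset_k)
        auc = (
            decoder_auc(tr, t_zero_ms=events[i]) if np.isfinite(events[i]) else np.nan
        )
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition.value,
                "query": t.report_query.value,
                "t_action_ms": events[i],
                "crossing_ms": cross,
                "objective_intent_ms": oit,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def trials_with_auc(bundle: SessionBundle) -> list[tuple]:
    """(trial, AUC) pairs for the tertile analysis, all conditions pooled."""
    events = action_reference_times(bundle)
    out = []
    for i, t in enumerate(bundle.trials):
        tr = bundle.decoder_traces.get(t.trial_id)
        if tr is None or not np.isfinite(events[i]):
            continue
        out.append((t, decoder_auc(tr, t_zero_ms=events[i])))
    return out


def standardized_auc_pairs(
    bundle: SessionBundle, conditions: Sequence[Condition]
) -> list[tuple]:
    """(trial, z-scored AUC) pairs with AUC standardized within each
    condition.

    Decoder AUC differs systematically between conditions (e.g. the
    no-action chain collapses early, the no-effect chain holds longer);
    standardizing within condition before pooling isolates per-trial
    decoding quality, the quantity the report-binding analysis sorts on.
    """
    pairs = [(t, a) for t, a in trials_with_auc(bundle) if t.condition in conditions]
    by_cond: dict[Condition, list[float]] = {}
    for t, a in pairs:
        by_cond.setdefault(t.condition, []).append(a)
    zstats = {c: (float(np.mean(v)), float(np.std(v)) or 1.0) for c, v in by_cond.items()}
    return [
        (t, (a - zstats[t.condition][0]) / zstats[t.condition][1]) for t, a in pairs
    ]


def fit_session_sigmoids(
    bundle: SessionBundle,
    window: tuple[float, float] = (-2000.0, 200.0),
    bin_ms: float = 10.0,
    slot_ms: float = DEFAULT_SLOT_MS,
    max_units: Optional[int] = None,
    unit_screen_r2: Optional[float] = 0.5,
) -> list[SigmoidFit]:
    """Fit the logistic change-point model per (sorted unit x trial).

    Two-stage procedure: each unit's *average* report-aligned rate is
    fit first, and only units whose average fit exceeds
    ``unit_screen_r2`` (with a positive step) contribute single-trial
    fits — otherwise trial fits from unresponsive units pass the
    retention threshold on smooth noise and place change-points at
    arbitrary times.  Set ``unit_screen_r2=None`` to fit every unit.

    Fits are aligned to the reported intention time on intention-report
    trials; rates are smoothed at the session kernel on a ``bin_ms``
    grid (10 ms by default — well below the 50 ms kernel SD).
    """
    rep = report_times(bundle, ReportQuery.INTENTION)
    trial_idx = np.flatnonzero(np.isfinite(rep))
    n_trials = len(bundle.trials)
    w0, w1 = window
    fits: list[SigmoidFit] = []
    units = [st for st in bundle.spikes if st.is_sorted_unit]
    if max_units is not None:
        units = units[:max_units]
    for st in units:
        counts = bin_session_spikes(st, n_trials, slot_ms, bin_ms)
        rates = smooth_counts(counts, bundle.config.smoothing_sd_ms, bin_ms)
        rows, t_grid = [], None
        for i in trial_idx:
            b0 = int(round((rep[i] + w0) / bin_ms))
            b1 = int(round((rep[i] + w1) / bin_ms))
            if b0 < 0 or b1 > rates.shape[1]:
                continue
            y = rates[i, b0:b1]
            if t_grid is None:
                t_grid = w0 + np.arange(y.size) * bin_ms
            rows.append((i, y))
        if not rows:
            continue
        if unit_screen_r2 is not None:
            avg = np.mean([y for _, y in rows], axis=0)
            unit_fit = fit_sigmoid(t_grid, avg, unit_id=st.unit_id)
            if not (
                unit_fit.valid
                and unit_fit.r_squared > unit_screen_r2
                and unit_fit.f_i > 0
            ):
                continue
        for i, y in rows:
            fits.append(
                fit_sigmoid(
                    t_grid, y, trial_id=bundle.trials[i].trial_id, unit_id=st.unit_id
                )
            )
    return fits


def pre_action_spike_counts(
    bundle: SessionBundle,
    window_ms: float = 1000.0,
    slot_ms: float = DEFAULT_SLOT_MS,
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Per sorted unit: spike counts in the second before action, on
    intention-report trials, with the matching report offsets.

    Returns (counts_per_unit as (n_trials,) arrays, report offsets,
    unit ids).
    """
    cfg = bundle.config
    events = action_reference_times(bundle)
    sel = [
        i
        for i, t in enumerate(bundle.trials)
        if t.report_query is ReportQuery.INTENTION
        and t.report_units is not None
        and np.isfinite(events[i])
    ]
    offsets = np.array(
        [
            report_to_event_relative_time(
                bundle.trials[i],
                reference_event_time(bundle.trials[i], ReportQuery.INTENTION, cfg),
                cfg,
            )
            for i in sel
        ]
    )
    slot_starts = np.array(sel) * slot_ms
    counts_per_unit, unit_ids = [], []
    for st in bundle.spikes:
        if not st.is_sorted_unit:
            continue
        times = st.spike_times_ms
        lo = slot_starts + events[sel] - window_ms
        hi = slot_starts + events[sel]
        counts = np.searchsorted(times, hi) - np.searchsorted(times, lo)
        counts_per_unit.append(counts.astype(float))
        unit_ids.append(st.unit_id)
    return counts_per_unit, offsets, unit_ids
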