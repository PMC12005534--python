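"""Domain types, clock/time conventions, and session-bundle I/O.

Conventions used throughout the package:

* All times are in milliseconds, relative to trial start (t = 0).
  Analysis windows aligned to an event use 0 = alignment event and
  negative times for "before".  Bins are half-open ``[t, t + bin)``.
* The Libet clock completes a full cycle in ``clock_cycle_ms``
  (default 2,560 ms) and carries ``clock_units`` ticks (default 60,
  positions 0-60 overlapping at "noon").  Each trial starts with the
  clock hand at a random position ``clock_phase_units``.
* A subjective report is a clock position in ``[0, clock_units)``.
  Because a trial spans several clock cycles, a reported position maps
  to many candidate times; the occurrence nearest the objective event
  is taken, so event-relative offsets always land in
  ``(-cycle/2, +cycle/2]``.

A session bundle on disk is a directory::

    config.json
    trials.csv          trial_id, condition, report_query, clock_phase_units,
                        t_action_ms, t_tone_ms, t_decoder_intent_ms, report_units
    spikes.csv          unit_id, channel, is_sorted_unit, spike_time_ms
    decoder/<trial>.csv t_ms, value          (one file per trial)
    lfp/<trial>.csv     t_ms, ch0, ch1, ...  (optional)

Missing values are written as empty fields, never sentinel numbers.
An alternative single-container dialect stores all traces in ``traces.h5``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ReportQuery",
    "TraceKind",
    "ExperimentConfig",
    "Trial",
    "SpikeTrain",
    "ContinuousTrace",
    "SessionBundle",
    "ValidationError",
    "clock_units_to_ms",
    "ms_to_clock_units",
    "clock_position_at",
    "report_to_event_relative_time",
    "reference_event_time",
    "read_session_bundle",
    "write_session_bundle",
]


class ValidationError(ValueError):
    """A bundle or record violates the schema or a domain invariant."""


class Condition(str, Enum):
    """Which elements of the intentional chain are present in a trial.

    I = intention, A = action (real hand closing via NMES), E = effect
    (auditory tone).  ``IAE`` is the full chain; the other conditions
    bypass one or more elements.
    """

    IAE = "IAE"
    AE = "AE"
    IE = "IE"
    IA = "IA"
    A_ONLY = "A_ONLY"
    E_ONLY = "E_ONLY"

    @property
    def has_intention(self) -> bool:
        return self in (Condition.IAE, Condition.IE, Condition.IA)

    @property
    def has_action(self) -> bool:
        return self in (Condition.IAE, Condition.AE, Condition.IA, Condition.A_ONLY)

    @property
    def has_effect(self) -> bool:
        return self in (Condition.IAE, Condition.AE, Condition.IE, Condition.E_ONLY)


class ReportQuery(str, Enum):
    """Which element of the chain the subject timestamps on the clock."""

    INTENTION = "INTENTION"
    ACTION = "ACTION"
    EFFECT = "EFFECT"
    NONE = "NONE"


class TraceKind(str, Enum):
    DECODER = "DECODER"
    LFP = "LFP"
    RAW = "RAW"


#: report queries that are meaningful for each condition
VALID_QUERIES = {
    Condition.IAE: (ReportQuery.INTENTION, ReportQuery.ACTION, ReportQuery.EFFECT),
    Condition.AE: (ReportQuery.ACTION, ReportQuery.EFFECT),
    Condition.IE: (ReportQuery.INTENTION, ReportQuery.EFFECT),
    Condition.IA: (ReportQuery.INTENTION, ReportQuery.ACTION),
    Condition.A_ONLY: (ReportQuery.ACTION,),
    Condition.E_ONLY: (ReportQuery.EFFECT,),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Session-level constants of the experiment and its analyses.

    Parameters
    ----------
    clock_cycle_ms:
        Duration of a full Libet-clock cycle (2,560 ms in the task).
    clock_units:
        Ticks per cycle; reports are positions in ``[0, clock_units)``.
    tone_delay_ms:
        Latency from action (or decoder threshold in no-action trials)
        to the auditory effect.
    sampling_rate_hz:
        Acquisition rate of raw neural data and reference for LFP.
    decoder_bin_ms:
        Width of the movement-decoder output bins.
    mua_bin_ms:
        Spike binning resolution for rate estimates.
    smoothing_sd_ms:
        SD of the Gaussian kernel used to smooth binned spikes.
    onset_k:
        Evoked-response onset threshold, in multiples of baseline SD.
    """

    clock_cycle_ms: float = 2560.0
    clock_units: int = 60
    tone_delay_ms: float = 300.0
    sampling_rate_hz: float = 30000.0
    decoder_bin_ms: float = 100.0
    mua_bin_ms: float = 1.0
    smoothing_sd_ms: float = 50.0
    onset_k: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "clock_cycle_ms",
            "tone_delay_ms",
            "sampling_rate_hz",
            "decoder_bin_ms",
            "mua_bin_ms",
            "smoothing_sd_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.clock_units < 2:
            raise ValidationError("clock_units must be >= 2")
        if self.onset_k <= 0:
            raise ValidationError("onset_k must be > 0")

    @property
    def ms_per_unit(self) -> float:
        return self.clock_cycle_ms / self.clock_units

    def to_dict(self) -> dict:
        return {
            "clock_cycle_ms": self.clock_cycle_ms,
            "clock_units": self.clock_units,
            "tone_delay_ms": self.tone_delay_ms,
            "sampling_rate_hz": self.sampling_rate_hz,
            "decoder_bin_ms": self.decoder_bin_ms,
            "mua_bin_ms": self.mua_bin_ms,
            "smoothing_sd_ms": self.smoothing_sd_ms,
            "onset_k": self.onset_k,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


@dataclass(frozen=True)
class Trial:
    """One trial: condition, objective event times, clock state, report.

    ``t_action_ms`` is absent for E_ONLY trials (no movement) and for IE
    trials (NMES disabled; ``t_decoder_intent_ms`` and the tone time are
    still defined).  ``report_units`` is the clock position reported
    after the trial, absent when ``report_query`` is NONE.
    """

    trial_id: str
    condition: Condition
    report_query: ReportQuery
    clock_phase_units: float
    t_action_ms: Optional[float] = None
    t_tone_ms: Optional[float] = None
    t_decoder_intent_ms: Optional[float] = None
    report_units: Optional[float] = None

    def validate(self, config: ExperimentConfig) -> None:
        cond, query = self.condition, self.report_query
        if not 0 <= self.clock_phase_units < config.clock_units:
            raise ValidationError(
                f"trial {self.trial_id}: clock_phase_units outside [0, clock_units)"
            )
        if self.report_units is not None and not (
            0 <= self.report_units < config.clock_units
        ):
            raise ValidationError(
                f"trial {self.trial_id}: report_units outside [0, clock_units)"
            )
        if query is not ReportQuery.NONE and query not in VALID_QUERIES[cond]:
            raise ValidationError(
                f"trial {self.trial_id}: query {query.value} invalid for {cond.value}"
            )
        if cond.has_action and cond is not Condition.IE and self.t_action_ms is None:
            raise ValidationError(f"trial {self.trial_id}: {cond.value} requires t_action_ms")
        if not cond.has_action and self.t_action_ms is not None:
            raise ValidationError(
                f"trial {self.trial_id}: {cond.value} must not carry t_action_ms"
            )
        if cond.has_effect and self.t_tone_ms is None:
            raise ValidationError(f"trial {self.trial_id}: {cond.value} requires t_tone_ms")
        if not cond.has_effect and self.t_tone_ms is not None:
            raise ValidationError(
                f"trial {self.trial_id}: {cond.value} must not carry t_tone_ms"
            )
        if cond.has_intention and self.t_decoder_intent_ms is None:
            raise ValidationError(
                f"trial {self.trial_id}: {cond.value} requires t_decoder_intent_ms"
            )
        if (
            cond is not Condition.IE
            and self.t_action_ms is not None
            and self.t_tone_ms is not None
        ):
            if not math.isclose(
                self.t_tone_ms - self.t_action_ms, config.tone_delay_ms, abs_tol=1e-9
            ):
                raise ValidationError(
                    f"trial {self.trial_id}: t_tone - t_action != tone_delay"
                )


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms, trial-relative) for one unit or channel."""

    unit_id: str
    channel: int
    spike_times_ms: np.ndarray
    is_sorted_unit: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times_ms, dtype=float)
        object.__setattr__(self, "spike_times_ms", times)
        if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times must be nondecreasing and >= 0"
            )
        if not 1 <= self.channel <= 96:
            raise ValidationError(f"unit {self.unit_id}: channel outside 1..96")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_ms.size)


@dataclass(frozen=True)
class ContinuousTrace:
    """Uniformly sampled trace: decoder output, LFP, or raw snippet.

    ``values`` has shape ``(n_samples,)`` for DECODER and
    ``(n_channels, n_samples)`` for LFP/RAW.  Decoder traces are scores
    in [-1, 1] at 100 ms bins (10 Hz); zero-crossing triggers movement.
    """

    kind: TraceKind
    fs_hz: float
    t0_ms: float
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")
        if self.kind is TraceKind.DECODER:
            if vals.ndim != 1:
                raise ValidationError("decoder trace must be 1-D")
            bad = np.flatnonzero((vals < -1) | (vals > 1))
            if bad.size:
                raise ValidationError(
                    f"decoder values outside [-1, 1] at samples {bad[:5].tolist()}"
                )
        elif vals.ndim != 2:
            raise ValidationError(f"{self.kind.value} trace must be 2-D (channels x samples)")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[-1])

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs_hz

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs_hz


@dataclass
class SessionBundle:
    """One experimental or synthetic session."""

    config: ExperimentConfig
    trials: list[Trial] = field(default_factory=list)
    spikes: list[SpikeTrain] = field(default_factory=list)
    decoder_traces: dict[str, ContinuousTrace] = field(default_factory=dict)
    lfp: dict[str, ContinuousTrace] = field(default_factory=dict)
    raw: dict[str, ContinuousTrace] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValidationError("trial_ids are not unique")
        for t in self.trials:
            t.validate(self.config)
        known = set(ids)
        for label, traces in (("decoder", self.decoder_traces), ("lfp", self.lfp)):
            for tid in traces:
                if tid not in known:
                    raise ValidationError(f"{label} trace references unknown trial {tid}")

    def trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def trials_in(self, *conditions: Condition) -> list[Trial]:
        return [t for t in self.trials if t.condition in conditions]


# ---------------------------------------------------------------------------
# clock conversions


def clock_units_to_ms(units: float, config: ExperimentConfig) -> float:
    """Convert a clock position (ticks) to time along the cycle (ms)."""
    if not 0 <= units <= config.clock_units:
        raise ValueError(f"clock units {units} outside [0, {config.clock_units}]")
    return units * config.clock_cycle_ms / config.clock_units


def ms_to_clock_units(t_ms: float, config: ExperimentConfig) -> float:
    """Inverse of :func:`clock_units_to_ms` on ``[0, cycle)``."""
    if not 0 <= t_ms <= config.clock_cycle_ms:
        raise ValueError(f"time {t_ms} outside [0, {config.clock_cycle_ms}]")
    return t_ms * config.clock_units / config.clock_cycle_ms


def clock_position_at(t_ms: float, phase_units: float, config: ExperimentConfig) -> float:
    """Clock-hand position (ticks, in [0, units)) at trial time ``t_ms``."""
    return (phase_units + t_ms / config.ms_per_unit) % config.clock_units


def report_to_event_relative_time(
    trial: Trial, event_time_ms: float, config: ExperimentConfig
) -> float:
    """Signed offset (ms) of the reported clock position from an event.

    The reported position recurs once per cycle; the occurrence nearest
    ``event_time_ms`` is selected, so the result is guaranteed to lie in
    ``(-cycle/2, +cycle/2]``.  Negative = the report points to a time
    before the event.
    """
    if trial.report_units is None:
        raise ValidationError(f"trial {trial.trial_id} has no report")
    if event_time_ms is None:
        raise ValidationError(f"trial {trial.trial_id}: event time absent")
    pos_at_event = clock_position_at(event_time_ms, trial.clock_phase_units, config)
    delta_units = (trial.report_units - pos_at_event) % config.clock_units
    # wrap to (-units/2, +units/2]
    if delta_units > config.clock_units / 2:
        delta_units -= config.clock_units
    return delta_units * config.ms_per_unit


def reference_event_time(trial: Trial, query: ReportQuery, config: ExperimentConfig) -> float:
    """Objective event time used as the reference for a report offset.

    Intention and action reports are referenced to action time (in
    no-action IE trials, to the time movement would have occurred:
    tone time minus the tone delay); effect reports to tone time.
    """
    if query is ReportQuery.EFFECT:
        if trial.t_tone_ms is None:
            raise ValidationError(f"trial {trial.trial_id}: no tone time")
        return trial.t_tone_ms
    if trial.t_action_ms is not None:
        return trial.t_action_ms
    if trial.t_tone_ms is not None:
        return trial.t_tone_ms - config.tone_delay_ms
    raise ValidationError(f"trial {trial.trial_id}: no action reference")


# ---------------------------------------------------------------------------
# bundle I/O

_TRIAL_COLUMNS = [
    "trial_id",
    "condition",
    "report_query",
    "clock_phase_units",
    "t_action_ms",
    "t_tone_ms",
    "t_decoder_intent_ms",
    "report_units",
]


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def write_session_bundle(bundle: SessionBundle, path, traces: str = "csv") -> None:
    """Write a bundle to a directory; ``traces`` selects 'csv' or 'h5'."""
    bundle.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(json.dumps(bundle.config.to_dict(), indent=1))

    rows = []
    for t in bundle.trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition.value,
                "report_query": t.report_query.value,
                "clock_phase_units": t.clock_phase_units,
                "t_action_ms": t.t_action_ms,
                "t_tone_ms": t.t_tone_ms,
                "t_decoder_intent_ms": t.t_decoder_intent_ms,
                "report_units": t.report_units,
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        root / "trials.csv", index=False, float_format="%.17g"
    )

    spike_rows = {
        "unit_id": [],
        "channel": [],
        "is_sorted_unit": [],
        "spike_time_ms": [],
    }
    for st in bundle.spikes:
        n = st.n_spikes
        spike_rows["unit_id"].extend([st.unit_id] * n)
        spike_rows["channel"].extend([st.channel] * n)
        spike_rows["is_sorted_unit"].extend([int(st.is_sorted_unit)] * n)
        spike_rows["spike_time_ms"].extend(st.spike_times_ms.tolist())
    pd.DataFrame(spike_rows).to_csv(root / "spikes.csv", index=False, float_format="%.17g")
    # units with zero spikes need their identity preserved
    empties = [
        {"unit_id": st.unit_id, "channel": st.channel, "is_sorted_unit": int(st.is_sorted_unit)}
        for st in bundle.spikes
        if st.n_spikes == 0
    ]
    pd.DataFrame(
        empties, columns=["unit_id", "channel", "is_sorted_unit"]
    ).to_csv(root / "units_empty.csv", index=False)

    if traces == "h5":
        _write_traces_h5(bundle, root / "traces.h5")
    elif traces == "csv":
        _write_traces_csv(bundle, root)
    else:
        raise ValueError(f"unknown traces dialect {traces!r}")


def _write_traces_csv(bundle: SessionBundle, root: Path) -> None:
    if bundle.decoder_traces:
        d = root / "decoder"
        d.mkdir(exist_ok=True)
        for tid, tr in bundle.decoder_traces.items():
            pd.DataFrame({"t_ms": tr.times_ms, "value": tr.values}).to_csv(
                d / f"{tid}.csv", index=False, float_format="%.17g"
            )
    if bundle.lfp:
        d = root / "lfp"
        d.mkdir(exist_ok=True)
        for tid, tr in bundle.lfp.items():
            df = pd.DataFrame({"t_ms": tr.times_ms})
            for ch in range(tr.values.shape[0]):
                df[f"ch{ch}"] = tr.values[ch]
            df.to_csv(d / f"{tid}.csv", index=False, float_format="%.17g")


def _write_traces_h5(bundle: SessionBundle, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for group_name, traces in (("decoder", bundle.decoder_traces), ("lfp", bundle.lfp)):
            g = f.create_group(group_name)
            for tid, tr in traces.items():
                ds = g.create_dataset(tid, data=tr.values)
                ds.attrs["fs_hz"] = tr.fs_hz
                ds.attrs["t0_ms"] = tr.t0_ms


def read_session_bundle(path) -> SessionBundle:
    """Read a bundle directory written by :func:`write_session_bundle`."""
    root = Path(path)
    cfg_path = root / "config.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing required file: {cfg_path}")
    config = ExperimentConfig.from_dict(json.loads(cfg_path.read_text()))

    trials_path = root / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"missing required file: {trials_path}")
    tdf = pd.read_csv(trials_path, dtype={"trial_id": str}, float_precision="round_trip")
    trials = []
    for row in tdf.itertuples(index=False):
        trials.append(
            Trial(
                trial_id=row.trial_id,
                condition=Condition(row.condition),
                report_query=ReportQuery(row.report_query),
                clock_phase_units=float(row.clock_phase_units),
                t_action_ms=_opt(row.t_action_ms),
                t_tone_ms=_opt(row.t_tone_ms),
                t_decoder_intent_ms=_opt(row.t_decoder_intent_ms),
                report_units=_opt(row.report_units),
            )
        )

    spikes_path = root / "spikes.csv"
    if not spikes_path.exists():
        raise FileNotFoundError(f"missing required file: {spikes_path}")
    sdf = pd.read_csv(spikes_path, dtype={"unit_id": str}, float_precision="round_trip")
    spikes = []
    if len(sdf):
        for unit_id, grp in sdf.groupby("unit_id", sort=False):
            spikes.append(
                SpikeTrain(
                    unit_id=str(unit_id),
                    channel=int(grp["channel"].iloc[0]),
                    spike_times_ms=np.sort(grp["spike_time_ms"].to_numpy(float)),
                    is_sorted_unit=bool(grp["is_sorted_unit"].iloc[0]),
                )
            )
    empty_path = root / "units_empty.csv"
    if empty_path.exists():
        edf = pd.read_csv(empty_path, dtype={"unit_id": str})
        for row in edf.itertuples(index=False):
            spikes.append(
                SpikeTrain(
                    unit_id=str(row.unit_id),
                    channel=int(row.channel),
                    spike_times_ms=np.array([]),
                    is_sorted_unit=bool(row.is_sorted_unit),
                )
            )

    bundle = SessionBundle(config=config, trials=trials, spikes=spikes)

    h5_path = root / "traces.h5"
    if h5_path.exists():
        _read_traces_h5(bundle, h5_path)
    else:
        _read_traces_csv(bundle, root)
    bundle.validate()
    return bundle


def _read_traces_csv(bundle: SessionBundle, root: Path) -> None:
    dec_dir = root / "decoder"
    if dec_dir.is_dir():
        for f in sorted(dec_dir.glob("*.csv")):
            df = pd.read_csv(f, float_precision="round_trip")
            t = df["t_ms"].to_numpy(float)
            fs = 1000.0 / (t[1] - t[0]) if len(t) > 1 else 10.0
            bundle.decoder_traces[f.stem] = ContinuousTrace(
                kind=TraceKind.DECODER,
                fs_hz=fs,
                t0_ms=float(t[0]),
                values=df["value"].to_numpy(float),
            )
    lfp_dir = root / "lfp"
    if lfp_dir.is_dir():
        for f in sorted(lfp_dir.glob("*.csv")):
            df = pd.read_csv(f, float_precision="round_trip")
            t = df["t_ms"].to_numpy(float)
            chans = [c for c in df.columns if c.startswith("ch")]
            fs = 1000.0 / (t[1] - t[0]) if len(t) > 1 else 1000.0
            bundle.lfp[f.stem] = ContinuousTrace(
                kind=TraceKind.LFP,
                fs_hz=fs,
                t0_ms=float(t[0]),
                values=np.vstack([df[c].to_numpy(float) for c in chans]),
            )


def _read_traces_h5(bundle: SessionBundle, path: Path) -> None:
    import h5py

    with h5py.File(path, "r") as f:
        for group_name, kind, store in (
            ("decoder", TraceKind.DECODER, bundle.decoder_traces),
            ("lfp", TraceKind.LFP, bundle.lfp),
        ):
            if group_name not in f:
                continue
            for tid, ds in f[group_name].items():
                store[tid] = ContinuousTrace(
                    kind=kind,
                    fs_hz=float(ds.attrs["fs_hz"]),
                    t0_ms=float(ds.attrs["t0_ms"]),
                    values=ds[()],
                )
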