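"""Spiking analyses: rate estimation, evoked-onset detection, report-
perturbation robustness, sliding spike-count correlations, and
single-trial sigmoid (logistic change-point) fitting.

Rates are estimated by binning spikes in 1 ms intervals and convolving
with a unit-area Gaussian kernel (SD 50 ms, truncated at +/-4 SD), so the
integral of the rate trace equals the spike count for interior spikes.

The sigmoid model for a single trial x unit is

    f(t) = f_I / (1 + exp(-(t - t0) / alpha)) + f_b

with f_b the baseline rate, f_I the step amplitude, t0 the change-point
time relative to the reported intention, and alpha the steepness scale
(small alpha = step-like, large alpha = ramp-like).  Fits are least
squares over a coarse (t0, alpha) grid — with baseline/amplitude solved
linearly at each node — followed by bounded local refinement from the
best grid starts, so the returned optimum never falls above any grid
start's residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit

from intentchain.session_model import ExperimentConfig, SpikeTrain

__all__ = [
    "RateTrace",
    "MuaAverage",
    "SigmoidFit",
    "PerturbationCurve",
    "FitSummary",
    "bin_spikes",
    "bin_and_smooth",
    "bin_session_spikes",
    "align_rates",
    "align_and_average",
    "evoked_onset",
    "perturbation_robustness",
    "sliding_spikecount_correlation",
    "fit_sigmoid",
    "summarize_fits",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateTrace:
    """Smoothed firing rate on a uniform 1 ms grid."""

    t_ms: np.ndarray
    rate_hz: np.ndarray
    unit_id: str = ""
    trial_id: str = ""
    alignment: str = "trial_start"


@dataclass(frozen=True)
class MuaAverage:
    """Trial-averaged aligned rate with S.E.M. per bin."""

    t_ms: np.ndarray
    mean_rate_hz: np.ndarray
    sem_hz: np.ndarray
    n_trials: int
    alignment: str = "event"


@dataclass(frozen=True)
class SigmoidFit:
    f_i: float
    f_b: float
    t0_ms: float
    alpha_ms: float
    r_squared: float
    trial_id: str = ""
    unit_id: str = ""
    valid: bool = True


@dataclass(frozen=True)
class PerturbationCurve:
    widths_ms: np.ndarray
    degraded: np.ndarray
    max_tolerated_width_ms: float


@dataclass(frozen=True)
class FitSummary:
    retained: list[SigmoidFit]
    n_retained: int
    mean_t0_ms: float
    median_t0_ms: float
    mean_alpha_ms: float
    median_alpha_ms: float
    t0_values: np.ndarray
    alpha_values: np.ndarray


# ---------------------------------------------------------------------------
# rate estimation


def _gaussian_kernel(sd_ms: float, bin_ms: float) -> np.ndarray:
    half = int(np.ceil(4 * sd_ms / bin_ms))
    x = np.arange(-half, half + 1) * bin_ms
    k = np.exp(-0.5 * (x / sd_ms) ** 2)
    return k / k.sum()


def bin_spikes(spike_times_ms: np.ndarray, duration_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """Spike counts on a half-open uniform grid [0, duration)."""
    n_bins = int(np.round(duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(np.asarray(spike_times_ms, float), bins=edges)
    return counts.astype(float)


def bin_and_smooth(
    spike_train: SpikeTrain | np.ndarray,
    duration_ms: float,
    config: Optional[ExperimentConfig] = None,
    trial_id: str = "",
) -> RateTrace:
    """1 ms binning followed by Gaussian smoothing, scaled to Hz."""
    config = config or ExperimentConfig()
    times = spike_train.spike_times_ms if isinstance(spike_train, SpikeTrain) else spike_train
    counts = bin_spikes(times, duration_ms, config.mua_bin_ms)
    kernel = _gaussian_kernel(config.smoothing_sd_ms, config.mua_bin_ms)
    rate = np.convolve(counts, kernel, mode="same") * (1000.0 / config.mua_bin_ms)
    t = np.arange(counts.size) * config.mua_bin_ms
    uid = spike_train.unit_id if isinstance(spike_train, SpikeTrain) else ""
    return RateTrace(t_ms=t, rate_hz=rate, unit_id=uid, trial_id=trial_id)


def smooth_counts(counts: np.ndarray, sd_ms: float = 50.0, bin_ms: float = 1.0) -> np.ndarray:
    """Smooth binned counts (rows = trials) into rates in Hz."""
    kernel = _gaussian_kernel(sd_ms, bin_ms)
    c = np.atleast_2d(np.asarray(counts, float))
    out = np.empty_like(c)
    for i in range(c.shape[0]):
        out[i] = np.convolve(c[i], kernel, mode="same")
    out *= 1000.0 / bin_ms
    return out if np.asarray(counts).ndim == 2 else out[0]


def bin_session_spikes(
    spike_train: SpikeTrain, n_trials: int, slot_ms: float, bin_ms: float = 1.0
) -> np.ndarray:
    """Per-trial binned counts (n_trials, slot bins) from a session-timeline train."""
    n_bins = int(np.round(slot_ms / bin_ms))
    out = np.zeros((n_trials, n_bins))
    times = spike_train.spike_times_ms
    trial_idx = np.floor(times / slot_ms).astype(int)
    rel = times - trial_idx * slot_ms
    bins = np.floor(rel / bin_ms).astype(int)
    ok = (trial_idx >= 0) & (trial_idx < n_trials) & (bins < n_bins)
    np.add.at(out, (trial_idx[ok], bins[ok]), 1.0)
    return out


# ---------------------------------------------------------------------------
# alignment & averaging


def align_rates(
    rate_matrix: np.ndarray,
    event_times_ms: np.ndarray,
    window: tuple[float, float],
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Align per-trial traces (rows) to per-trial events.

    Returns ``(aligned, kept)``: aligned rows cover ``[window[0],
    window[1])`` around each trial's event (0 = event); trials whose
    trace does not cover the window are dropped with a log entry.
    """
    rates = np.atleast_2d(np.asarray(rate_matrix, float))
    events = np.asarray(event_times_ms, float)
    w0 = int(np.round(window[0] / bin_ms))
    w1 = int(np.round(window[1] / bin_ms))
    n_out = w1 - w0
    rows, kept = [], []
    for i, ev in enumerate(events):
        c = int(np.round(ev / bin_ms))
        lo, hi = c + w0, c + w1
        if lo < 0 or hi > rates.shape[1]:
            logger.info("trial %d dropped: window outside trace", i)
            continue
        rows.append(rates[i, lo:hi])
        kept.append(i)
    if not rows:
        return np.empty((0, n_out)), np.array([], int)
    return np.vstack(rows), np.asarray(kept, int)


def align_and_average(
    rate_matrix: np.ndarray,
    event_times_ms: np.ndarray,
    window: tuple[float, float],
    bin_ms: float = 1.0,
    alignment: str = "event",
) -> MuaAverage:
    """Trial-wise alignment then mean and S.E.M. per bin."""
    aligned, kept = align_rates(rate_matrix, event_times_ms, window, bin_ms)
    if aligned.shape[0] == 0:
        raise ValueError("no trial covers the requested window")
    t = np.arange(aligned.shape[1]) * bin_ms + window[0]
    mean = aligned.mean(axis=0)
    n = aligned.shape[0]
    sem = aligned.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return MuaAverage(t_ms=t, mean_rate_hz=mean, sem_hz=sem, n_trials=n, alignment=alignment)


# ---------------------------------------------------------------------------
# evoked onset


def evoked_onset(
    mua: MuaAverage,
    baseline_window: tuple[float, float] = (-2000.0, -1500.0),
    k: float = 5.0,
    sustain_ms: float = 10.0,
) -> Optional[float]:
    """First time the mean rate exceeds baseline by k x baseline SD,
    sustained for at least ``sustain_ms``; None if never.

    The noise level is the SD of the mean trace over the baseline
    window; the search starts at the end of the baseline window.
    """
    t = mua.t_ms
    base = (t >= baseline_window[0]) & (t < baseline_window[1])
    if base.sum() < 2:
        raise ValueError("baseline window not covered by trace")
    noise = float(mua.mean_rate_hz[base].std(ddof=1))
    if noise == 0.0:
        raise ValueError("zero baseline variance")
    thr = float(mua.mean_rate_hz[base].mean()) + k * noise
    bin_ms = float(t[1] - t[0])
    need = max(1, int(np.round(sustain_ms / bin_ms)))
    search = np.flatnonzero(t >= baseline_window[1])
    above = mua.mean_rate_hz > thr
    run = 0
    for i in search:
        if above[i]:
            run += 1
            if run >= need:
                return float(t[i - need + 1])
        else:
            run = 0
    return None


# ---------------------------------------------------------------------------
# perturbation robustness


def perturbation_robustness(
    rate_matrix: np.ndarray,
    report_times_ms: np.ndarray,
    rng: np.random.Generator,
    widths_ms: Optional[np.ndarray] = None,
    window: tuple[float, float] = (-500.0, 500.0),
    alpha: float = 0.01,
    min_sig_bins: int = 10,
    bin_ms: float = 1.0,
) -> PerturbationCurve:
    """Robustness of report-aligned averages to report jitter.

    For each width w the reports are jittered uniformly on [-w, +w] and
    the realigned trials are compared bin-by-bin (unpaired t) against
    the unperturbed alignment; a width is "degraded" when at least
    ``min_sig_bins`` bins differ at p < alpha.  The tolerated width is
    the largest non-degraded width.
    """
    widths = np.arange(10.0, 1001.0, 10.0) if widths_ms is None else np.asarray(widths_ms, float)
    if np.any(np.diff(widths) <= 0):
        raise ValueError("widths must be strictly increasing")
    reports = np.asarray(report_times_ms, float)
    if reports.size < 10:
        raise ValueError("need >= 10 trials")
    orig, kept = align_rates(rate_matrix, reports, window, bin_ms)
    degraded = np.zeros(widths.size, dtype=bool)
    for j, w in enumerate(widths):
        jit = rng.uniform(-w, w, size=reports.size)
        pert, kept_p = align_rates(rate_matrix, reports + jit, window, bin_ms)
        if pert.shape[0] < 2:
            degraded[j] = True
            continue
        tt = stats.ttest_ind(pert, orig, axis=0, equal_var=False)
        degraded[j] = int(np.sum(tt.pvalue < alpha)) >= min_sig_bins
    tolerated = widths[~degraded]
    max_tol = float(tolerated.max()) if tolerated.size else 0.0
    return PerturbationCurve(widths_ms=widths, degraded=degraded, max_tolerated_width_ms=max_tol)


# ---------------------------------------------------------------------------
# sliding spike-count correlations


def sliding_spikecount_correlation(
    counts_per_unit: Sequence[np.ndarray],
    report_values: np.ndarray,
    centers_ms: np.ndarray,
    window_ms: float = 1000.0,
    bin_ms: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Pearson correlation between windowed spike counts and reports.

    ``counts_per_unit``: per unit, an (n_trials, T) binned-count matrix
    on a common event-aligned grid starting at ``t_grid0``; windows of
    ``window_ms`` are centered on each value of ``centers_ms`` expressed
    on that same grid (index units: center index = center/bin_ms).
    Windows with zero count variance yield r = nan, not significant.

    Returns dict with ``r`` and ``p`` of shape (n_units, n_centers) and
    ``n_significant`` per center.
    """
    reports = np.asarray(report_values, float)
    n_trials = reports.size
    if n_trials < 3:
        raise ValueError("need >= 3 trials")
    centers = np.asarray(centers_ms, float)
    half = window_ms / 2.0
    r_all, p_all = [], []
    ry = reports - reports.mean()
    sy = np.sqrt((ry**2).sum())
    for counts in counts_per_unit:
        c = np.asarray(counts, float)
        csum = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(c, axis=1)], axis=1)
        T = c.shape[1]
        lo = np.clip(np.round((centers - half) / bin_ms).astype(int), 0, T)
        hi = np.clip(np.round((centers + half) / bin_ms).astype(int), 0, T)
        win_counts = csum[:, hi] - csum[:, lo]  # (n_trials, n_centers)
        x = win_counts - win_counts.mean(axis=0)
        sx = np.sqrt((x**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x * ry[:, None]).sum(axis=0) / (sx * sy)
        r = np.where(sx == 0, np.nan, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = r * np.sqrt((n_trials - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n_trials - 2)
        p = np.where(np.isnan(r), 1.0, p)
        r_all.append(r)
        p_all.append(p)
    r_arr = np.vstack(r_all)
    p_arr = np.vstack(p_all)
    return {
        "r": r_arr,
        "p": p_arr,
        "n_significant": (p_arr < alpha).sum(axis=0),
        "centers_ms": centers,
    }


# ---------------------------------------------------------------------------
# sigmoid change-point fitting


def _sigmoid(t, f_b, f_i, t0, alpha):
    return f_b + f_i * expit((t - t0) / alpha)


def _linear_solve(s: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Best (f_b, f_i) for fixed sigmoid shape s; returns (f_b, f_i, sse)."""
    A = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    f_b, f_i = coef
    if f_b < 0:  # project onto the f_b >= 0 constraint
        f_b = 0.0
        denom = float((s**2).sum())
        f_i = float((s * y).sum() / denom) if denom > 0 else 0.0
    resid = y - (f_b + f_i * s)
    return float(f_b), float(f_i), float((resid**2).sum())


def fit_sigmoid(
    t_ms: np.ndarray,
    rate_hz: np.ndarray,
    t0_grid_step_ms: float = 100.0,
    alpha_grid_ms: Sequence[float] = (5.0, 20.0, 60.0, 150.0),
    n_refine: int = 3,
    trial_id: str = "",
    unit_id: str = "",
) -> SigmoidFit:
    """Least-squares logistic change-point fit of a single-trial rate.

    Multi-start: a (t0, alpha) grid with the linear parameters solved in
    closed form at each node, then bounded local refinement
    (``scipy.optimize.least_squares``) from the best ``n_refine``
    starts.  Bounds: f_b >= 0, alpha > 0, t0 inside the window.
    Deterministic.
    """
    t = np.asarray(t_ms, float)
    y = np.asarray(rate_hz, float)
    w0, w1 = float(t[0]), float(t[-1])
    t0_grid = np.arange(w0, w1 + 1e-9, t0_grid_step_ms)

    starts = []
    for t0 in t0_grid:
        for alpha in alpha_grid_ms:
            s = expit((t - t0) / alpha)
            f_b, f_i, sse = _linear_solve(s, y)
            starts.append((sse, f_b, f_i, t0, alpha))
    starts.sort(key=lambda x: x[0])
    grid_best_sse = starts[0][0]

    lb = [0.0, -np.inf, w0, 1e-3]
    ub = [np.inf, np.inf, w1, np.inf]

    def resid(x):
        return _sigmoid(t, *x) - y

    best = None
    for sse, f_b, f_i, t0, alpha in starts[:n_refine]:
        x0 = [max(f_b, 0.0), f_i, float(np.clip(t0, w0, w1)), max(alpha, 1e-3)]
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        sse_ref = float((sol.fun**2).sum())
        if best is None or sse_ref < best[0]:
            best = (sse_ref, sol.x)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, -np.inf, trial_id, unit_id, valid=False)
    sse, x = best
    if sse > grid_best_sse + 1e-9:  # refinement must not fall behind the grid
        sse, f_b, f_i, t0, alpha = starts[0]
        x = [f_b, f_i, t0, alpha]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse < 1e-12 else -np.inf)
    f_b, f_i, t0, alpha = (float(v) for v in x)
    return SigmoidFit(
        f_i=f_i, f_b=f_b, t0_ms=t0, alpha_ms=alpha, r_squared=r2,
        trial_id=trial_id, unit_id=unit_id, valid=True,
    )


def summarize_fits(fits: Sequence[SigmoidFit], r2_threshold: float = 0.5) -> FitSummary:
    """Retain fits with r^2 strictly above threshold; summarize t0, alpha."""
    retained = [f for f in fits if f.valid and f.r_squared > r2_threshold]
    t0 = np.array([f.t0_ms for f in retained])
    alpha = np.array([f.alpha_ms for f in retained])
    return FitSummary(
        retained=retained,
        n_retained=len(retained),
        mean_t0_ms=float(t0.mean()) if t0.size else np.nan,
        median_t0_ms=float(np.median(t0)) if t0.size else np.nan,
        mean_alpha_ms=float(alpha.mean()) if alpha.size else np.nan,
        median_alpha_ms=float(np.median(alpha)) if alpha.size else np.nan,
        t0_values=t0,
        alpha_values=alpha,
    )
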