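"""The BMI movement-decoding chain and its derived analyses.

Pipeline stages mirror the online system: NMES artifact blanking on the
raw 30 kHz signal, mean-wavelet-power (MWP) features per 100 ms bin,
a sparsity-pruned non-linear SVM per movement with scores mapped to
[-1, 1], and the derived per-trial measures — zero threshold crossing
(movement trigger), objective intention time (first excursion above
5 SD of rest noise), surrogate crossing rate, decoder AUC, and
condition time-course divergence.

MWP uses an 11-level discrete wavelet transform (Daubechies, db4 by
default); detail levels 3-6 cover the multi-unit band
``fs/2^(l+1) .. fs/2^l`` = 234.375 Hz-3.75 kHz at 30 kHz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.svm import SVC, LinearSVC

from intentchain.session_model import ContinuousTrace, TraceKind

__all__ = [
    "MwpFeatures",
    "MovementClassifier",
    "blank_artifacts",
    "extract_mwp",
    "wavelet_level_band",
    "train_classifier",
    "classify",
    "threshold_crossing",
    "objective_intention_time",
    "estimate_rest_noise",
    "surrogate_crossing_rate",
    "decoder_auc",
    "timecourse_divergence",
]


@dataclass(frozen=True)
class MwpFeatures:
    """Normalized mean wavelet power, one row per 100 ms bin."""

    t_ms: np.ndarray
    values: np.ndarray  # (n_bins, n_channels)


# ---------------------------------------------------------------------------
# artifact blanking


def blank_artifacts(
    raw: np.ndarray,
    fs_hz: float = 30000.0,
    monitor_channels: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    threshold_uv: float = 500.0,
    min_channels: int = 4,
    blank_ms: float = 3.5,
    n_monitor: int = 12,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Detect NMES artifacts and blank them on all channels.

    An artifact is a sample where the absolute amplitude exceeds
    ``threshold_uv`` simultaneously on at least ``min_channels`` of the
    ``n_monitor`` monitored channels (drawn once per session with the
    session seed when not supplied).  Each detected artifact is blanked
    over ``blank_ms`` (105 samples at 30 kHz) centered on its onset, by
    linear interpolation across the gap on *all* channels.

    Returns the cleaned array and the list of blanked [start, stop)
    sample intervals.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 2:
        raise ValueError("raw must be (channels, samples)")
    n_ch, n_samp = x.shape
    if n_ch < n_monitor:
        raise ValueError(f"need >= {n_monitor} channels")
    w = int(round(blank_ms * fs_hz / 1000.0))
    if n_samp < w:
        raise ValueError("snippet shorter than blank window")
    if monitor_channels is None:
        rng = rng or np.random.default_rng(0)
        monitor_channels = rng.choice(n_ch, size=n_monitor, replace=False)
    mon = np.asarray(monitor_channels, int)

    hot = (np.abs(x[mon]) > threshold_uv).sum(axis=0) >= min_channels
    det = np.flatnonzero(hot)
    intervals: list[tuple[int, int]] = []
    cleaned = x.copy()
    i = 0
    while i < det.size:
        onset = det[i]
        start = max(0, onset - w // 2)
        stop = min(n_samp, start + w)
        intervals.append((int(start), int(stop)))
        # skip detections swallowed by this blank
        while i < det.size and det[i] < stop:
            i += 1
    for start, stop in intervals:
        left = start - 1
        right = stop
        for c in range(n_ch):
            v0 = cleaned[c, left] if left >= 0 else cleaned[c, right if right < n_samp else stop - 1]
            v1 = cleaned[c, right] if right < n_samp else v0
            cleaned[c, start:stop] = np.linspace(v0, v1, stop - start + 2)[1:-1]
    return cleaned, intervals


# ---------------------------------------------------------------------------
# MWP features


def wavelet_level_band(fs_hz: float, level: int) -> tuple[float, float]:
    """Frequency band (Hz) of DWT detail level ``level``: [fs/2^(l+1), fs/2^l)."""
    return fs_hz / 2 ** (level + 1), fs_hz / 2**level


def _level_bin_energy(coeffs: np.ndarray, level: int, n_samples: int, samples_per_bin: int,
                      n_bins: int) -> np.ndarray:
    """Mean squared detail-coefficient energy per time bin for one level."""
    e = np.repeat(np.abs(coeffs) ** 2, 2**level)
    if e.size < n_samples:
        e = np.pad(e, (0, n_samples - e.size), mode="edge")
    e = e[:n_samples]
    return e[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin).mean(axis=1)


def extract_mwp(
    raw: np.ndarray,
    fs_hz: float = 30000.0,
    levels: Sequence[int] = (3, 4, 5, 6),
    bin_ms: float = 100.0,
    wavelet: str = "db4",
    n_levels: int = 11,
    normalize: bool = True,
    baseline_bins: int = 100,
) -> MwpFeatures:
    """Mean wavelet power per channel per 100 ms bin.

    Per channel: an ``n_levels``-deep DWT; the squared detail
    coefficients of ``levels`` are averaged within each bin and across
    levels.  When ``normalize`` is set, each channel is z-scored
    against a trailing baseline of up to ``baseline_bins`` bins (10 s
    at 100 ms bins), falling back to the global statistics while the
    history is short.
    """
    x = np.atleast_2d(np.asarray(raw, float))
    n_ch, n_samp = x.shape
    samples_per_bin = int(round(bin_ms * fs_hz / 1000.0))
    n_bins = n_samp // samples_per_bin
    if n_bins < 1:
        raise ValueError("snippet shorter than one bin")
    max_level = pywt.dwt_max_level(n_samp, pywt.Wavelet(wavelet).dec_len)
    depth = min(n_levels, max_level)
    out = np.zeros((n_bins, n_ch))
    for c in range(n_ch):
        decomp = pywt.wavedec(x[c], wavelet, level=depth)
        # decomp = [cA_depth, cD_depth, ..., cD_1]
        per_level = []
        for lev in levels:
            if lev > depth:
                continue
            coeffs = decomp[depth - lev + 1]
            per_level.append(
                _level_bin_energy(coeffs, lev, n_samp, samples_per_bin, n_bins)
            )
        out[:, c] = np.mean(per_level, axis=0)
    if normalize:
        norm = np.empty_like(out)
        for i in range(n_bins):
            lo = max(0, i - baseline_bins)
            ref = out[lo:i] if i - lo >= 10 else out
            mu = ref.mean(axis=0)
            sd = ref.std(axis=0)
            sd[sd == 0] = 1.0
            norm[i] = (out[i] - mu) / sd
        out = norm
    t = np.arange(n_bins) * bin_ms
    return MwpFeatures(t_ms=t, values=out)


# ---------------------------------------------------------------------------
# classifier


class MovementClassifier(BaseEstimator):
    """Per-movement sparsity-pruned RBF-SVM over MWP features.

    One binary model per movement class (every non-rest label in ``y``),
    each preceded by an L1-based feature ranking that keeps the
    ``sparsity`` fraction of MWP features judged most valuable.  Decision
    scores are scaled by the largest training-set margin and clipped to
    [-1, 1]; a score of -1 reads "at rest", +1 "performing the movement",
    and zero-crossing is the movement trigger.

    Attributes (after fit)
    ----------------------
    movements_ : list of movement labels
    masks_ : dict movement -> boolean retained-feature mask
    models_ : dict movement -> fitted SVC
    scales_ : dict movement -> decision-function scale
    """

    def __init__(
        self,
        sparsity: float = 0.5,
        C: float = 1.0,
        gamma: str | float = "scale",
        l1_C: float = 0.1,
        rest_label: str = "rest",
        random_state: Optional[int] = None,
    ):
        self.sparsity = sparsity
        self.C = C
        self.gamma = gamma
        self.l1_C = l1_C
        self.rest_label = rest_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        classes = np.unique(y)
        movements = [c for c in classes if c != self.rest_label]
        if len(classes) < 2 or not movements:
            raise ValueError("need rest plus at least one movement class")
        for c in classes:
            if (y == c).sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_keep = max(1, int(round(self.sparsity * X.shape[1])))
        self.movements_ = list(movements)
        self.masks_, self.models_, self.scales_ = {}, {}, {}
        for m in movements:
            yb = (y == m).astype(int)
            ranker = LinearSVC(
                penalty="l1", dual=False, C=self.l1_C, max_iter=5000,
                random_state=self.random_state,
            ).fit(X, yb)
            importance = np.abs(ranker.coef_).ravel()
            order = np.argsort(importance)[::-1]
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[order[:n_keep]] = True
            model = SVC(
                kernel="rbf", C=self.C, gamma=self.gamma, random_state=self.random_state
            ).fit(X[:, mask], yb)
            df = model.decision_function(X[:, mask])
            self.masks_[m] = mask
            self.models_[m] = model
            self.scales_[m] = float(np.max(np.abs(df))) or 1.0
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X, movement: Optional[str] = None) -> np.ndarray:
        """Clipped, scaled decision scores in [-1, 1] for one movement."""
        if not hasattr(self, "models_"):
            raise ValueError("classifier is not fitted")
        movement = movement or self.movements_[0]
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimensionality mismatch")
        df = self.models_[movement].decision_function(X[:, self.masks_[movement]])
        return np.clip(df / self.scales_[movement], -1.0, 1.0)

    def predict(self, X):
        """Most likely movement per bin, or rest if no score is positive."""
        scores = np.column_stack([self.decision_scores(X, m) for m in self.movements_])
        best = np.argmax(scores, axis=1)
        out = np.array([self.movements_[i] for i in best], dtype=object)
        out[scores.max(axis=1) < 0] = self.rest_label
        return out

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    sparsity_level: float = 0.5,
    random_state: Optional[int] = None,
) -> MovementClassifier:
    """Fit a :class:`MovementClassifier` (functional wrapper)."""
    return MovementClassifier(sparsity=sparsity_level, random_state=random_state).fit(
        np.asarray(features, float), np.asarray(labels)
    )


def classify(
    model: MovementClassifier,
    features: MwpFeatures | np.ndarray,
    movement: str = "HC",
    bin_ms: float = 100.0,
) -> ContinuousTrace:
    """Score a feature stream; one decoder value per 100 ms bin."""
    if isinstance(features, MwpFeatures):
        X = features.values
        t0 = float(features.t_ms[0])
    else:
        X = np.asarray(features, float)
        t0 = 0.0
    scores = model.decision_scores(X, movement)
    return ContinuousTrace(kind=TraceKind.DECODER, fs_hz=1000.0 / bin_ms, t0_ms=t0, values=scores)


# ---------------------------------------------------------------------------
# trace measures


def threshold_crossing(trace: ContinuousTrace) -> Optional[float]:
    """Start time of the first bin with score >= 0 after a sub-zero bin."""
    v = trace.values
    t = trace.times_ms
    for i in range(1, v.size):
        if v[i] >= 0 and v[i - 1] < 0:
            return float(t[i])
    return None


def objective_intention_time(
    trace: ContinuousTrace, noise_mean: float, noise_sd: float, k: float = 5.0
) -> Optional[float]:
    """First bin exceeding rest noise mean + k x SD; None if never."""
    if noise_sd <= 0:
        raise ValueError("zero-variance noise estimate")
    above = trace.values > noise_mean + k * noise_sd
    idx = np.flatnonzero(above)
    return float(trace.times_ms[idx[0]]) if idx.size else None


def estimate_rest_noise(
    traces: Sequence[ContinuousTrace],
    rest_window_ms: tuple[float, float] = (0.0, 2000.0),
    min_total_s: float = 5.0,
) -> tuple[float, float]:
    """Pooled mean/SD of decoder output over rest (inter-trial) segments."""
    pooled = []
    for tr in traces:
        t = tr.times_ms
        seg = tr.values[(t >= rest_window_ms[0]) & (t < rest_window_ms[1])]
        pooled.append(seg)
    x = np.concatenate(pooled)
    total_s = x.size / traces[0].fs_hz
    if total_s < min_total_s:
        raise ValueError(f"only {total_s:.1f} s of rest data; need >= {min_total_s} s")
    return float(x.mean()), float(x.std(ddof=1))


def surrogate_crossing_rate(
    trace: ContinuousTrace,
    request_windows_ms: Sequence[tuple[float, float]],
    n_shifts: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of randomly re-placed request windows containing a
    zero-crossing (sub-zero bin followed by a bin >= 0)."""
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    t = trace.times_ms
    v = trace.values
    dur = float(t[-1] - t[0])
    crossings = t[1:][(v[1:] >= 0) & (v[:-1] < 0)]
    hits = 0
    total = 0
    for w0, w1 in request_windows_ms:
        length = w1 - w0
        if length > dur:
            raise ValueError("window longer than trace")
        for _ in range(n_shifts):
            start = rng.uniform(t[0], t[-1] - length)
            total += 1
            if np.any((crossings >= start) & (crossings < start + length)):
                hits += 1
    return hits / total


def decoder_auc(trace: ContinuousTrace, window_ms: tuple[float, float] = (-2000.0, 2000.0),
                t_zero_ms: float = 0.0) -> float:
    """Time-average (trapezoidal) of the trace over a peri-event window.

    ``t_zero_ms`` shifts the window to an event (e.g. action time); the
    result is bounded in [-1, 1] because the trace is.
    """
    t = trace.times_ms - t_zero_ms
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if sel.sum() < 2:
        raise ValueError("empty AUC window")
    ts, vs = t[sel], trace.values[sel]
    return float(np.trapezoid(vs, ts) / (ts[-1] - ts[0]))


def timecourse_divergence(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    t_ms: np.ndarray,
    alpha: float = 0.01,
) -> tuple[Optional[float], np.ndarray]:
    """Per-bin unpaired t-tests, Bonferroni-corrected over bins.

    Returns (earliest significant time or None, corrected p per bin).
    """
    a = np.atleast_2d(np.asarray(traces_a, float))
    b = np.atleast_2d(np.asarray(traces_b, float))
    if a.shape[1] != b.shape[1] or a.shape[1] != len(t_ms):
        raise ValueError("groups must share the time grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 trials per group")
    tt = stats.ttest_ind(a, b, axis=0)
    p_corr = np.minimum(tt.pvalue * a.shape[1], 1.0)
    sig = np.flatnonzero(p_corr < alpha)
    first = float(t_ms[sig[0]]) if sig.size else None
    return first, p_corr
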