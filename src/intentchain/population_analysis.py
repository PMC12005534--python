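"""Population-level analyses.

Two complementary views of the 96-channel ensemble:

* PCA latent trajectories — PCA is fit on time-concatenated
  condition-average firing rates (channels as variables), conditions are
  projected into the top-2 space, and condition separability is
  summarized as the 2-D Euclidean distance between trajectories with
  bootstrap (resample trials, refit PCA) confidence bands.
* LFP band power — Morlet continuous-wavelet power maps
  (0.5-30 Hz, baseline-normalized per frequency) and a cross-validated
  SVM separating baseline power (-2,200..-2,000 ms) from induced power
  at 100 ms steps over -2,000..+2,000 ms around the action, per
  frequency band (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pywt
from scipy import signal, stats
from sklearn.decomposition import PCA
from sklearn.model_selection import GroupKFold, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "LatentTrajectory",
    "DistanceCurve",
    "PowerMap",
    "BandDecodingCurve",
    "BANDS",
    "condition_pca",
    "bootstrap_distance",
    "lfp_power_map",
    "band_classification",
    "band_curve_difference",
    "cv_accuracy",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class LatentTrajectory:
    condition: str
    pc_scores: np.ndarray  # (2, n_time)
    variance_explained: float


@dataclass(frozen=True)
class DistanceCurve:
    t_ms: np.ndarray
    mean_distance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int


@dataclass(frozen=True)
class PowerMap:
    t_ms: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # (n_freqs, n_time)


@dataclass(frozen=True)
class BandDecodingCurve:
    band: str
    t_ms: np.ndarray
    accuracy: np.ndarray
    p_values: np.ndarray
    first_significant_ms: Optional[float]


# ---------------------------------------------------------------------------
# PCA trajectories


def condition_pca(
    condition_rates: dict[str, np.ndarray], n_components: int = 2
) -> tuple[list[LatentTrajectory], float]:
    """Fit PCA on time-concatenated condition-average rates.

    ``condition_rates`` maps condition label to an (n_channels, n_time)
    average-rate matrix on a common grid.  Channels are the variables;
    the concatenated time courses of all conditions are the samples.
    Returns per-condition top-2 trajectories and the variance fraction
    captured by the retained pair.
    """
    labels = list(condition_rates)
    mats = [np.asarray(condition_rates[c], float) for c in labels]
    n_ch = mats[0].shape[0]
    if any(m.shape[0] != n_ch for m in mats):
        raise ValueError("conditions must share the channel dimension")
    X = np.concatenate([m.T for m in mats], axis=0)  # (sum n_time, n_channels)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < n_components:
        raise ValueError("rate matrix rank below number of components")
    pca = PCA(n_components=n_components).fit(X)
    var = float(pca.explained_variance_ratio_[:2].sum())
    trajectories = [
        LatentTrajectory(c, pca.transform(m.T).T[:2], var)
        for c, m in zip(labels, mats)
    ]
    return trajectories, var


def _mean_traj_distance(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """2-D PCA distance between two condition-average rate matrices."""
    X = np.concatenate([mean_a.T, mean_b.T], axis=0)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        return np.zeros(mean_a.shape[1])
    pca = PCA(n_components=2).fit(X)
    ta = pca.transform(mean_a.T)
    tb = pca.transform(mean_b.T)
    return np.linalg.norm(ta - tb, axis=1)


def bootstrap_distance(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    t_ms: np.ndarray,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> DistanceCurve:
    """Bootstrap the 2-D latent distance between two conditions.

    Inputs are (n_trials, n_channels, n_time) rate stacks.  Each draw
    resamples trials with replacement within each condition, recomputes
    the condition means, refits PCA on the concatenated means, and
    measures the per-bin Euclidean distance in the top-2 space; the 95%
    CI is the percentile band over draws.
    """
    a = np.asarray(trials_a, float)
    b = np.asarray(trials_b, float)
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise ValueError("need >= 5 trials per condition")
    rng = rng or np.random.default_rng(0)
    dists = np.empty((n_boot, a.shape[2]))
    for i in range(n_boot):
        ia = rng.integers(0, a.shape[0], a.shape[0])
        ib = rng.integers(0, b.shape[0], b.shape[0])
        dists[i] = _mean_traj_distance(a[ia].mean(axis=0), b[ib].mean(axis=0))
    return DistanceCurve(
        t_ms=np.asarray(t_ms, float),
        mean_distance=dists.mean(axis=0),
        ci_low=np.percentile(dists, 2.5, axis=0),
        ci_high=np.percentile(dists, 97.5, axis=0),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# LFP power


def lfp_power_map(
    values: np.ndarray,
    fs_hz: float,
    freqs_hz: Optional[np.ndarray] = None,
    t0_ms: float = 0.0,
    decimate_to_hz: float = 125.0,
    baseline_window_ms: Optional[tuple[float, float]] = None,
    wavelet: str = "cmor1.5-1.0",
    normalize: bool = True,
) -> PowerMap:
    """Morlet continuous-wavelet power, baseline-normalized per frequency.

    ``values`` is (n_channels, n_samples) or (n_samples,); channels are
    averaged after the power transform.  The signal is decimated (with
    anti-alias filtering) to about ``decimate_to_hz`` before the CWT.
    Power is divided by its per-frequency mean over ``baseline_window_ms``
    (whole trace if None).
    """
    x = np.atleast_2d(np.asarray(values, float))
    freqs = np.arange(0.5, 30.5, 0.5) if freqs_hz is None else np.asarray(freqs_hz, float)
    q = max(1, int(fs_hz // decimate_to_hz))
    if q > 1:
        x = signal.decimate(x, q, axis=1, zero_phase=True)
    fs = fs_hz / q
    if fs < 2 * freqs.max():
        raise ValueError("sampling rate below Nyquist for requested frequencies")
    n = x.shape[1]
    if n / fs < 2.0 / freqs.min():
        raise ValueError("window shorter than 2 cycles at the lowest frequency")
    dt = 1.0 / fs
    scales = pywt.frequency2scale(wavelet, freqs * dt)
    power = np.zeros((freqs.size, n))
    for c in range(x.shape[0]):
        coef, _ = pywt.cwt(x[c], scales, wavelet, sampling_period=dt)
        power += np.abs(coef) ** 2
    power /= x.shape[0]
    t_ms = t0_ms + np.arange(n) * 1000.0 / fs
    if normalize:
        if baseline_window_ms is not None:
            sel = (t_ms >= baseline_window_ms[0]) & (t_ms < baseline_window_ms[1])
            ref = power[:, sel].mean(axis=1, keepdims=True)
        else:
            ref = power.mean(axis=1, keepdims=True)
        ref[ref == 0] = 1.0
        power = power / ref
    return PowerMap(t_ms=t_ms, freqs_hz=freqs, power=power)


# ---------------------------------------------------------------------------
# band classification


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    groups: Optional[np.ndarray] = None,
) -> float:
    """Cross-validated accuracy of an RBF SVM.

    With ``groups`` (e.g. the trial index of each sample), folds are
    split by group so that a trial's baseline and induced samples never
    straddle the train/test boundary — otherwise paired samples bias the
    estimate below chance under the null.
    """
    counts = np.bincount(np.asarray(y, int))
    if counts.min() < 2 or folds < 2:
        raise ValueError("fold size < 2")
    if groups is not None:
        k = min(folds, int(np.unique(groups).size))
        cv = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
        scores = cross_val_score(SVC(kernel="rbf"), X, y, cv=cv, groups=groups)
    else:
        k = min(folds, int(counts.min()))
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores = cross_val_score(SVC(kernel="rbf"), X, y, cv=cv)
    return float(scores.mean())


def band_classification(
    power_stack: np.ndarray,
    t_ms: np.ndarray,
    freqs_hz: np.ndarray,
    bands: Optional[dict[str, tuple[float, float]]] = None,
    baseline_window_ms: tuple[float, float] = (-2200.0, -2000.0),
    test_range_ms: tuple[float, float] = (-2000.0, 2000.0),
    step_ms: float = 100.0,
    folds: int = 10,
    alpha: float = 0.01,
    seed: int = 0,
) -> list[BandDecodingCurve]:
    """Baseline-vs-induced separability per band, per 100 ms step.

    ``power_stack`` is (n_trials, n_freqs, n_time) of per-trial power
    maps on an action-aligned grid ``t_ms`` (0 = action).  For each band
    and step, an SVM classifies trials' mean band power at baseline
    against the test step (10-fold CV); significance against chance is a
    one-sided binomial test at p < alpha.
    """
    P = np.asarray(power_stack, float)
    if P.shape[0] < 20:
        raise ValueError("need >= 20 trials")
    bands = bands or BANDS
    t = np.asarray(t_ms, float)
    steps = np.arange(test_range_ms[0], test_range_ms[1], step_ms)
    base_sel = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    curves = []
    for name, (f0, f1) in bands.items():
        fsel = (freqs_hz >= f0) & (freqs_hz < f1)
        band_p = P[:, fsel, :].mean(axis=1)  # (n_trials, n_time)
        x_base = band_p[:, base_sel].mean(axis=1)
        accs, pvals = [], []
        for s in steps:
            wsel = (t >= s) & (t < s + step_ms)
            x_test = band_p[:, wsel].mean(axis=1)
            X = np.concatenate([x_base, x_test])[:, None]
            y = np.concatenate([np.zeros(P.shape[0], int), np.ones(P.shape[0], int)])
            groups = np.tile(np.arange(P.shape[0]), 2)
            acc = cv_accuracy(X, y, folds=folds, seed=seed, groups=groups)
            n_total = y.size
            successes = int(round(acc * n_total))
            p = stats.binomtest(successes, n_total, 0.5, alternative="greater").pvalue
            accs.append(acc)
            pvals.append(float(p))
        accs = np.asarray(accs)
        pvals = np.asarray(pvals)
        sig = np.flatnonzero(pvals < alpha)
        curves.append(
            BandDecodingCurve(
                band=name,
                t_ms=steps,
                accuracy=accs,
                p_values=pvals,
                first_significant_ms=float(steps[sig[0]]) if sig.size else None,
            )
        )
    return curves


def band_curve_difference(
    curve_full: BandDecodingCurve,
    curve_reduced: BandDecodingCurve,
    power_full: Optional[np.ndarray] = None,
    power_reduced: Optional[np.ndarray] = None,
    n_perm: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Decodability difference between the full chain and a reduced
    condition, per test step.

    Returns the per-step accuracy difference (full - reduced).  When the
    per-trial power stacks and ``n_perm > 0`` are supplied, a permutation
    band is added: trial-condition labels are shuffled ``n_perm`` times
    and the 2.5/97.5 percentile of the null difference of group-mean
    band power (a cheap surrogate for refitting both classifiers per
    permutation) is reported per step.
    """
    if curve_full.band != curve_reduced.band:
        raise ValueError("curves must come from the same frequency band")
    if curve_full.t_ms.shape != curve_reduced.t_ms.shape or np.any(
        curve_full.t_ms != curve_reduced.t_ms
    ):
        raise ValueError("curves must share the step grid")
    out = {
        "band": curve_full.band,
        "t_ms": curve_full.t_ms,
        "accuracy_difference": curve_full.accuracy - curve_reduced.accuracy,
    }
    if n_perm and power_full is not None and power_reduced is not None:
        rng = rng or np.random.default_rng(0)
        pooled = np.concatenate([power_full, power_reduced])
        n_a = power_full.shape[0]
        diffs = np.empty((n_perm, pooled.shape[-1]))
        for i in range(n_perm):
            idx = rng.permutation(pooled.shape[0])
            diffs[i] = (
                pooled[idx[:n_a]].mean(axis=(0, 1)) - pooled[idx[n_a:]].mean(axis=(0, 1))
            )
        out["null_low"] = np.percentile(diffs, 2.5, axis=0)
        out["null_high"] = np.percentile(diffs, 97.5, axis=0)
    return out
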