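"""Clock-report statistics.

Per-condition subjective-timing offsets, binding contrasts between
conditions, the pairwise action-effect interval, and the decoder-AUC
tertile analysis of reports.

Offsets — not raw clock positions — are the unit of analysis: each
report is unwrapped to the occurrence of the reported clock position
nearest the objective event (see
:func:`intentchain.session_model.report_to_event_relative_time`), so all
offsets live in ``(-cycle/2, +cycle/2]``.  Intention and action reports
are referenced to the objective action time (or, in no-movement trials,
to the time movement would have occurred); effect reports to tone time.

"Targeted non-parametric statistics" are realized as two-sided Wilcoxon
rank-sum tests on the unwrapped offsets; the test is a swappable choice
for unpaired trial-level contrasts in a single-subject design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intentchain.session_model import (
    Condition,
    ExperimentConfig,
    ReportQuery,
    SessionBundle,
    Trial,
    reference_event_time,
    report_to_event_relative_time,
)

__all__ = [
    "ReportSummary",
    "BindingContrast",
    "AucSplitResult",
    "circular_median",
    "report_offsets",
    "summarize_reports",
    "contrast_conditions",
    "pairwise_action_effect_median",
    "auc_tertile_split",
]


@dataclass(frozen=True)
class ReportSummary:
    condition: Condition
    query: ReportQuery
    n: int
    median_offset_ms: float
    sem_ms: float


@dataclass(frozen=True)
class BindingContrast:
    condition_a: str
    condition_b: str
    query: ReportQuery
    delta_ms: float
    p_value: float
    test_name: str = "wilcoxon-rank-sum"


@dataclass(frozen=True)
class AucSplitResult:
    query: ReportQuery
    median_high_auc_ms: float
    median_low_auc_ms: float
    p_value: float
    n_per_tertile: int


def circular_median(values: Sequence[float], cycle: float) -> float:
    """In-sample circular median on a cycle of the given period.

    Returns the sample point minimizing the summed geodesic (shorter-arc)
    distance to all points; ties broken toward the smallest value.  The
    in-sample definition makes the minimizer exactly testable by brute
    force.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("circular_median of empty input")
    if cycle <= 0:
        raise ValueError("cycle must be > 0")
    diff = np.abs(v[:, None] - v[None, :]) % cycle
    geo = np.minimum(diff, cycle - diff)
    cost = geo.sum(axis=1)
    best = cost.min()
    return float(v[np.isclose(cost, best, rtol=0.0, atol=1e-9)].min())


def report_offsets(
    bundle: SessionBundle,
    condition: Condition,
    query: ReportQuery,
    trials: Optional[Iterable[Trial]] = None,
) -> np.ndarray:
    """Unwrapped event-relative report offsets (ms) for one condition x query."""
    cfg = bundle.config
    pool = bundle.trials if trials is None else list(trials)
    out = []
    for t in pool:
        if t.condition is condition and t.report_query is query and t.report_units is not None:
            event = reference_event_time(t, query, cfg)
            out.append(report_to_event_relative_time(t, event, cfg))
    return np.asarray(out, dtype=float)


def summarize_reports(bundle: SessionBundle) -> list[ReportSummary]:
    """One :class:`ReportSummary` per (condition, query) with any reports.

    The median is the in-sample circular median of event-relative
    offsets; the S.E.M. is the linear SD of the unwrapped offsets over
    sqrt(n) (valid because unwrapped offsets are far from the wrap
    boundary in this task).
    """
    cfg = bundle.config
    summaries = []
    for cond in Condition:
        for query in (ReportQuery.INTENTION, ReportQuery.ACTION, ReportQuery.EFFECT):
            off = report_offsets(bundle, cond, query)
            if off.size == 0:
                continue
            med = circular_median(off, cfg.clock_cycle_ms)
            sem = float(off.std(ddof=1) / np.sqrt(off.size)) if off.size > 1 else 0.0
            summaries.append(ReportSummary(cond, query, int(off.size), med, sem))
    return summaries


def contrast_conditions(
    offsets_a: Sequence[float],
    offsets_b: Sequence[float],
    cycle_ms: float = 2560.0,
    query: ReportQuery = ReportQuery.ACTION,
    label_a: str = "a",
    label_b: str = "b",
) -> BindingContrast:
    """Two-sided rank-sum contrast of unwrapped report offsets.

    ``delta_ms`` is circular_median(a) - circular_median(b).
    """
    a = np.asarray(offsets_a, dtype=float)
    b = np.asarray(offsets_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 trials per side")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.ranksums(a, b).pvalue)
    delta = circular_median(a, cycle_ms) - circular_median(b, cycle_ms)
    return BindingContrast(label_a, label_b, query, float(delta), p)


def pairwise_action_effect_median(
    action_estimates: Sequence[float], effect_estimates: Sequence[float]
) -> float:
    """Median over all cross pairs ``effect_j - action_i``.

    Inputs are subjective time estimates on a common (action-relative)
    axis; with accurate relative timing the result approaches the
    objective action-to-tone delay.
    """
    a = np.asarray(action_estimates, dtype=float)
    e = np.asarray(effect_estimates, dtype=float)
    if a.size == 0 or e.size == 0:
        raise ValueError("both estimate sets must be nonempty")
    return float(np.median((e[None, :] - a[:, None]).ravel()))


def auc_tertile_split(
    trials_with_auc: Sequence[tuple[Trial, float]],
    query: ReportQuery,
    config: ExperimentConfig,
) -> AucSplitResult:
    """Compare report offsets between top- and bottom-AUC trial tertiles.

    Trials (pooled across conditions for one judgment type) are sorted
    by decoder AUC; report offsets of the top third are contrasted with
    the bottom third by rank-sum.  Boundary ties are broken by a stable
    sort on trial_id.
    """
    usable = [
        (t, auc)
        for t, auc in trials_with_auc
        if t.report_query is query and t.report_units is not None
    ]
    if len(usable) < 6:
        raise ValueError("need >= 6 trials with AUC and reports")
    usable.sort(key=lambda p: p[0].trial_id)  # stable pre-sort on trial_id
    usable.sort(key=lambda p: p[1])
    k = len(usable) // 3

    def offsets(pairs) -> np.ndarray:
        return np.array(
            [
                report_to_event_relative_time(t, reference_event_time(t, query, config), config)
                for t, _ in pairs
            ]
        )

    low = offsets(usable[:k])
    high = offsets(usable[-k:])
    p = float(stats.ranksums(high, low).pvalue)
    return AucSplitResult(
        query=query,
        median_high_auc_ms=circular_median(high, config.clock_cycle_ms),
        median_low_auc_ms=circular_median(low, config.clock_cycle_ms),
        p_value=p,
        n_per_tertile=k,
    )


def summaries_to_frame(summaries: list[ReportSummary]) -> pd.DataFrame:
    """Tidy DataFrame view of report summaries (for CSV export)."""
    return pd.DataFrame(
        [
            {
                "condition": s.condition.value,
                "query": s.query.value,
                "n": s.n,
                "median_offset_ms": s.median_offset_ms,
                "sem_ms": s.sem_ms,
            }
            for s in summaries
        ]
    )
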