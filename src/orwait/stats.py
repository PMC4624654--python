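"""Wait-time statistics, multi-run aggregation, bootstrap and cost arithmetic.

Per-run summaries report, for each urgency class, the mean, SD, median,
empirical 95th percentile (nearest-rank) and maximum of post-burn-in wait
times, plus the run's overall room utilization.  Replicate runs of the
same scenario are aggregated as mean +/- SD across runs, matching the way
wait-time tables are conventionally reported.  Bootstrap resampling (100
replicates by default) provides an alternative uncertainty for the median
and 95th percentile of a single run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import MINUTES_PER_YEAR, Scenario, UrgencyClass
from .engine import SimResult

__all__ = [
    "ClassWaitStats",
    "WaitSummary",
    "RunAggregate",
    "nearest_rank_p95",
    "summarize_waits",
    "aggregate_runs",
    "bootstrap_uncertainty",
    "prob_wait_at_least",
    "annual_wait_hours",
    "annual_wait_hours_saved",
    "marginal_cost_analysis",
    "interarrival_histogram",
]

STATISTICS = ("mean", "sd", "median", "p95", "max")


def nearest_rank_p95(waits: np.ndarray) -> float:
    """Empirical 95th percentile by the nearest-rank rule.

    Returns the ceil(0.95 n)-th order statistic, which is always an
    observed value (printed wait tables are whole minutes).
    """
    w = np.sort(np.asarray(waits))
    if w.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    k = math.ceil(0.95 * w.size)
    return float(w[k - 1])


@dataclass(frozen=True)
class ClassWaitStats:
    n: int
    mean: float
    sd: float
    median: float
    p95: float
    max: float

    def get(self, stat: str) -> float:
        return getattr(self, stat)


@dataclass(frozen=True)
class WaitSummary:
    """One run's per-class wait statistics plus overall utilization."""

    per_class: dict[UrgencyClass, ClassWaitStats | None]
    utilization_pct: float
    scenario: Scenario | None = None


def summarize_waits(result: SimResult, burnin_min: int | None = None) -> WaitSummary:
    """Per-class wait statistics over served patients arriving post-burn-in.

    A class with no served post-burn-in patients is reported as absent
    (``None``), not as zeros.
    """
    burnin = result.scenario.burnin_min if burnin_min is None else burnin_min
    per_class: dict[UrgencyClass, ClassWaitStats | None] = {}
    for cls in UrgencyClass:
        m = (
            result.served_mask
            & (result.urgency == int(cls))
            & (result.arrival_min >= burnin)
        )
        w = (result.start_min[m] - result.arrival_min[m]).astype(float)
        if w.size == 0:
            per_class[cls] = None
            continue
        per_class[cls] = ClassWaitStats(
            n=int(w.size),
            mean=float(w.mean()),
            sd=float(w.std(ddof=1)) if w.size >= 2 else 0.0,
            median=float(np.median(w)),
            p95=nearest_rank_p95(w),
            max=float(w.max()),
        )
    return WaitSummary(
        per_class=per_class,
        utilization_pct=result.utilization_pct,
        scenario=result.scenario,
    )


@dataclass(frozen=True)
class RunAggregate:
    """Mean +/- SD of each statistic across replicate runs of one scenario."""

    per_class: dict[UrgencyClass, dict[str, tuple[float, float]]]
    utilization_pct: tuple[float, float]
    n_runs: int
    scenario: Scenario | None = None

    def value(self, cls: UrgencyClass, stat: str) -> float:
        return self.per_class[cls][stat][0]

    def sd(self, cls: UrgencyClass, stat: str) -> float:
        return self.per_class[cls][stat][1]


def aggregate_runs(summaries: Sequence[WaitSummary]) -> RunAggregate:
    """Aggregate replicate summaries of the same scenario as mean +/- SD."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicate summaries to aggregate")
    scen = summaries[0].scenario
    if any(s.scenario != scen for s in summaries[1:]):
        raise ValueError("cannot aggregate summaries from different scenarios")
    per_class: dict[UrgencyClass, dict[str, tuple[float, float]]] = {}
    for cls in UrgencyClass:
        stats_list = [s.per_class[cls] for s in summaries]
        if any(st is None for st in stats_list):
            continue
        per_class[cls] = {}
        for stat in STATISTICS:
            vals = np.array([st.get(stat) for st in stats_list])
            per_class[cls][stat] = (float(vals.mean()), float(vals.std(ddof=1)))
    utils = np.array([s.utilization_pct for s in summaries])
    return RunAggregate(
        per_class=per_class,
        utilization_pct=(float(utils.mean()), float(utils.std(ddof=1))),
        n_runs=len(summaries),
        scenario=scen,
    )


def bootstrap_uncertainty(
    waits: Sequence[float] | np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap SDs of the median and 95th percentile of a wait sample.

    Each of ``n_boot`` resamples draws ``len(waits)`` values with
    replacement; returns ``(sd_of_medians, sd_of_p95s)`` across resamples.
    """
    w = np.asarray(waits, dtype=float)
    if w.size == 0:
        raise ValueError("waits must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    medians = np.empty(n_boot)
    p95s = np.empty(n_boot)
    for b in range(n_boot):
        res = rng.choice(w, size=w.size, replace=True)
        medians[b] = np.median(res)
        p95s[b] = nearest_rank_p95(res)
    return float(medians.std(ddof=1)), float(p95s.std(ddof=1))


def prob_wait_at_least(waits: Sequence[float] | np.ndarray, threshold: float) -> float:
    """Fraction of waits greater than or equal to ``threshold`` minutes."""
    w = np.asarray(waits, dtype=float)
    if w.size == 0:
        raise ValueError("waits must be non-empty")
    return float((w >= threshold).mean())


def _one_result_wait_hours(result: SimResult, burnin: int) -> float:
    span = result.scenario.horizon_min - burnin
    if span < MINUTES_PER_YEAR:
        raise ValueError(
            "post-burn-in span must cover at least one simulated year "
            f"(got {span} min)"
        )
    m = result.served_mask & (result.arrival_min >= burnin)
    total_wait_min = float((result.start_min[m] - result.arrival_min[m]).sum())
    return total_wait_min * (MINUTES_PER_YEAR / span) / 60.0


def annual_wait_hours(
    results: SimResult | Sequence[SimResult],
    burnin_min: int | None = None,
) -> float:
    """Total patient waiting, in hours per simulated year, all classes pooled.

    Post-burn-in wait minutes are normalized to a 525,600-minute year and
    converted to hours; a list of replicate runs is averaged.
    """
    if isinstance(results, SimResult):
        results = [results]
    vals = []
    for r in results:
        burnin = r.scenario.burnin_min if burnin_min is None else burnin_min
        vals.append(_one_result_wait_hours(r, burnin))
    return float(np.mean(vals))


def annual_wait_hours_saved(
    results_before: SimResult | Sequence[SimResult],
    results_after: SimResult | Sequence[SimResult],
) -> float:
    """Annual waiting-hours saved moving from one scenario to another."""
    return annual_wait_hours(results_before) - annual_wait_hours(results_after)


@dataclass(frozen=True)
class MarginalCost:
    cost_per_year: float
    cost_per_hour_saved: float


def marginal_cost_analysis(
    delta_hours_saved: float,
    annual_full_time_cost: float,
    added_staffed_hours_per_day: float,
) -> MarginalCost:
    """Cost of extra staffed OR time per waiting-hour saved.

    ``annual_full_time_cost`` is the marginal cost of staffing one OR
    around the clock for a year; staffing it only ``added_staffed_hours_per_day``
    hours a day prorates that cost linearly.
    """
    if delta_hours_saved <= 0:
        raise ValueError("delta_hours_saved must be > 0")
    cost_per_year = annual_full_time_cost * added_staffed_hours_per_day / 24.0
    return MarginalCost(
        cost_per_year=cost_per_year,
        cost_per_hour_saved=cost_per_year / delta_hours_saved,
    )


def interarrival_histogram(
    arrival_minutes: Sequence[float] | np.ndarray,
    bin_width: int = 20,
) -> np.ndarray:
    """Histogram of successive inter-arrival gaps, pooled over classes.

    Bins are ``[0, w), [w, 2w), ...``; returns the count per bin starting
    at zero.  With Poisson arrivals the counts decay geometrically with
    ratio exp(-lambda * w).
    """
    a = np.sort(np.asarray(arrival_minutes, dtype=float))
    if a.size < 2:
        raise ValueError("need at least 2 arrivals to form inter-arrival gaps")
    gaps = np.diff(a)
    idx = (gaps // bin_width).astype(int)
    return np.bincount(idx)
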