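"""Minute-stepped Monte Carlo engine for OR wait times.

Conceptually the simulator steps through every minute of the horizon: it
releases rooms whose occupancy ends that minute, draws Poisson arrival
counts for each urgency class, and then fills any free staffed rooms with
the highest-priority eligible waiting patient (FIFO within a class).  A
case blocks a room for one contiguous block of ``duration + setup_cleanup
+ duration_delta`` minutes; a patient's wait ends the minute a room is
allocated.  The implementation pre-draws all arrivals and durations and
then advances event-to-event (arrival minutes, room releases, shift
boundaries), which is exactly equivalent to the naive minute loop because
the queue state can only change at those minutes.

Night minutes restrict which classes may *start* a case; running cases
always continue across shift changes, and starts (not occupancy) are
capped by the staffed room count of the start minute.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import (
    MINUTES_PER_DAY,
    PRIORITY_ORDER,
    ClassParams,
    ParamsMap,
    Scenario,
    UrgencyClass,
    validate_scenario,
)

__all__ = [
    "SimResult",
    "OfferedLoad",
    "draw_arrival_counts",
    "draw_duration",
    "lognormal_duration_sampler",
    "simulate",
    "run_replicates",
    "offered_load",
]

#: A duration sampler maps (class params, n draws, rng) -> continuous minutes.
DurationSampler = Callable[[ClassParams, int, np.random.Generator], np.ndarray]


def lognormal_duration_sampler(
    cp: ClassParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Default surgical-duration model: exp(Normal(meanlog, sdlog))."""
    return rng.lognormal(mean=cp.meanlog, sigma=cp.sdlog, size=size)


def draw_arrival_counts(
    rate: float, n_minutes: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Poisson(rate) arrival counts, one per minute."""
    if rate < 0:
        raise ValueError(f"arrival rate must be >= 0, got {rate}")
    return rng.poisson(rate, n_minutes)


def draw_duration(
    cp: ClassParams,
    rng: np.random.Generator,
    size: int | None = None,
    sampler: DurationSampler = lognormal_duration_sampler,
) -> np.ndarray | int:
    """Draw surgical durations, rounded to whole minutes (>= 1).

    The engine is minute-stepped, so continuous draws are rounded to the
    nearest minute (half up); the floor of one minute guarantees strictly
    positive durations.  Nearest rounding keeps the mean occupancy, and
    hence the utilization, equal to the continuous log-normal expectation.
    """
    n = 1 if size is None else size
    d = np.maximum(np.floor(sampler(cp, n, rng) + 0.5), 1).astype(np.int64)
    return int(d[0]) if size is None else d


@dataclass
class SimResult:
    """Outcome of one simulation run (struct-of-arrays over all patients).

    Arrays are aligned; patients are grouped by class (priority order)
    and sorted by arrival minute within each class.  ``start_min`` and
    ``wait_min`` are -1 for patients still waiting at the horizon.
    """

    scenario: Scenario
    seed: int | None
    urgency: np.ndarray          # int8 priority ranks
    arrival_min: np.ndarray      # int64
    duration_min: np.ndarray     # int64, whole minutes
    occupancy_min: np.ndarray    # int64, duration + setup + delta (>= 1)
    start_min: np.ndarray        # int64, -1 if pending
    busy_room_minutes: int
    capacity_room_minutes: int

    @property
    def wait_min(self) -> np.ndarray:
        w = self.start_min - self.arrival_min
        w[self.start_min < 0] = -1
        return w

    @property
    def served_mask(self) -> np.ndarray:
        return self.start_min >= 0

    @property
    def n_arrivals(self) -> int:
        return int(self.arrival_min.size)

    @property
    def n_served(self) -> int:
        return int(self.served_mask.sum())

    @property
    def n_pending(self) -> int:
        return self.n_arrivals - self.n_served

    @property
    def utilization_pct(self) -> float:
        if self.capacity_room_minutes == 0:
            return float("nan")
        return 100.0 * self.busy_room_minutes / self.capacity_room_minutes

    @property
    def unstable(self) -> bool:
        """Flag a growing backlog: over 1 % of arrivals never reached a room."""
        return self.n_arrivals > 0 and self.n_pending > max(
            50, 0.01 * self.n_arrivals
        )

    def class_waits(self, cls: UrgencyClass, post_burnin: bool = True) -> np.ndarray:
        """Served wait times for one class, optionally post-burn-in only."""
        m = self.served_mask & (self.urgency == int(cls))
        if post_burnin:
            m &= self.arrival_min >= self.scenario.burnin_min
        return (self.start_min[m] - self.arrival_min[m]).astype(np.int64)

    def arrivals_log(self, post_burnin: bool = False) -> dict[UrgencyClass, np.ndarray]:
        """Per-class sorted arrival minutes (for inter-arrival analysis)."""
        out = {}
        for cls in UrgencyClass:
            m = self.urgency == int(cls)
            if post_burnin:
                m &= self.arrival_min >= self.scenario.burnin_min
            out[cls] = np.sort(self.arrival_min[m])
        return out

    def to_frame(self, run: int | None = None) -> pd.DataFrame:
        """Per-patient table: run, urgency, arrival, duration, start, wait."""
        served = self.served_mask
        df = pd.DataFrame(
            {
                "urgency": [UrgencyClass(int(u)).name for u in self.urgency],
                "arrival_min": self.arrival_min,
                "duration_min": self.duration_min,
                "start_min": pd.array(
                    np.where(served, self.start_min, -1), dtype="Int64"
                ),
                "wait_min": pd.array(
                    np.where(served, self.start_min - self.arrival_min, -1),
                    dtype="Int64",
                ),
            }
        )
        df.loc[~served, ["start_min", "wait_min"]] = pd.NA
        if run is not None:
            df.insert(0, "run", run)
        return df.sort_values(
            ["arrival_min", "urgency"], kind="stable", ignore_index=True
        )


def _day_minutes_in(a: int, b: int, lo: int, hi: int) -> int:
    """Number of minutes t in [a, b) with lo <= t mod 1440 < hi."""

    def f(x: int) -> int:
        full, rem = divmod(x, MINUTES_PER_DAY)
        return full * (hi - lo) + min(max(rem - lo, 0), hi - lo)

    return f(b) - f(a)


def simulate(
    scenario: Scenario,
    params: ParamsMap,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    duration_sampler: DurationSampler = lognormal_duration_sampler,
) -> SimResult:
    """Run one replicate of the minute-stepped queue simulation.

    Within a minute, releases happen first, then arrivals, then room
    assignment; among simultaneous candidates the highest-priority,
    longest-waiting eligible patient starts first.  Patients arriving
    during burn-in are simulated (they warm the system) but are excluded
    from wait statistics downstream.
    """
    violations = validate_scenario(scenario)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))
    if rng is None:
        rng = np.random.default_rng(seed)

    horizon = scenario.horizon_min
    setup = scenario.setup_cleanup_min
    delta = scenario.duration_delta_min
    classes = list(PRIORITY_ORDER)
    K = len(classes)

    # Pre-draw all arrivals (per-minute Poisson counts) and durations.
    minutes_c: list[np.ndarray] = []
    dur_c: list[np.ndarray] = []
    occ_c: list[np.ndarray] = []
    for cls in classes:
        cp = params[cls]
        rate = cp.arrival_rate * scenario.volume_multiplier
        counts = draw_arrival_counts(rate, horizon, rng)
        idx = np.nonzero(counts)[0]
        mins = np.repeat(idx, counts[idx])
        d = draw_duration(cp, rng, size=mins.size, sampler=duration_sampler)
        minutes_c.append(mins)
        dur_c.append(d)
        occ_c.append(np.maximum(d + setup + delta, 1))

    starts_c = [np.full(m.size, -1, dtype=np.int64) for m in minutes_c]
    n_c = [m.size for m in minutes_c]

    night_ok = [cls in scenario.night_eligible_classes for cls in classes]
    lo, hi = scenario.day_window
    cap_day, cap_night = scenario.day_or_count, scenario.night_or_count

    releases: list[int] = []  # heap of room-release minutes
    occupied = 0
    heads = [0] * K  # next waiting patient per class
    enq = [0] * K    # next arrival not yet enqueued per class
    INF = 1 << 62

    def next_boundary(after: int) -> int:
        # Earliest shift boundary (day start or day end) strictly > after.
        day0 = (after // MINUTES_PER_DAY) * MINUTES_PER_DAY
        for b in (day0 + lo, day0 + hi, day0 + MINUTES_PER_DAY + lo):
            if b > after:
                return b
        return day0 + MINUTES_PER_DAY + hi  # unreachable for lo < hi

    t = -1
    while True:
        cand = releases[0] if releases else INF
        for k in range(K):
            if enq[k] < n_c[k]:
                m = minutes_c[k][enq[k]]
                if m < cand:
                    cand = m
        if any(heads[k] < enq[k] for k in range(K)):
            b = next_boundary(t)
            if b < cand:
                cand = b
        if cand >= horizon:
            break
        t = int(cand)

        while releases and releases[0] == t:
            heapq.heappop(releases)
            occupied -= 1
        for k in range(K):
            mk, nk = minutes_c[k], n_c[k]
            j = enq[k]
            while j < nk and mk[j] == t:
                j += 1
            enq[k] = j

        m = t % MINUTES_PER_DAY
        is_day = lo <= m < hi
        cap = cap_day if is_day else cap_night
        while occupied < cap:
            pick = -1
            for k in range(K):
                if heads[k] < enq[k] and (is_day or night_ok[k]):
                    pick = k
                    break
            if pick < 0:
                break
            i = heads[pick]
            heads[pick] = i + 1
            starts_c[pick][i] = t
            heapq.heappush(releases, t + int(occ_c[pick][i]))
            occupied += 1

    urgency = np.concatenate(
        [np.full(n_c[k], int(classes[k]), dtype=np.int8) for k in range(K)]
    ) if any(n_c) else np.empty(0, dtype=np.int8)
    arrival = np.concatenate(minutes_c) if any(n_c) else np.empty(0, dtype=np.int64)
    duration = np.concatenate(dur_c) if any(n_c) else np.empty(0, dtype=np.int64)
    occupancy = np.concatenate(occ_c) if any(n_c) else np.empty(0, dtype=np.int64)
    start = np.concatenate(starts_c) if any(n_c) else np.empty(0, dtype=np.int64)

    burnin = scenario.burnin_min
    served = start >= 0
    s, o = start[served], occupancy[served]
    busy = int(
        np.maximum(np.minimum(s + o, horizon) - np.maximum(s, burnin), 0).sum()
    )
    dmin = _day_minutes_in(burnin, horizon, lo, hi)
    capacity = dmin * cap_day + (horizon - burnin - dmin) * cap_night

    return SimResult(
        scenario=scenario,
        seed=seed,
        urgency=urgency,
        arrival_min=arrival.astype(np.int64),
        duration_min=duration,
        occupancy_min=occupancy,
        start_min=start,
        busy_room_minutes=busy,
        capacity_room_minutes=int(capacity),
    )


def run_replicates(
    scenario: Scenario,
    params: ParamsMap,
    n_runs: int | None = None,
    base_seed: int | None = None,
    duration_sampler: DurationSampler = lognormal_duration_sampler,
) -> list[SimResult]:
    """Run ``n_runs`` independent replicates seeded ``base_seed + i``."""
    n = scenario.n_runs if n_runs is None else n_runs
    s0 = scenario.base_seed if base_seed is None else base_seed
    return [
        simulate(scenario, params, seed=s0 + i, duration_sampler=duration_sampler)
        for i in range(n)
    ]


@dataclass(frozen=True)
class OfferedLoad:
    """Closed-form load check: expected busy rooms vs average staffed rooms."""

    expected_busy_rooms: float
    avg_staffed_rooms: float
    rho: float
    stable: bool


def offered_load(params: ParamsMap, scenario: Scenario) -> OfferedLoad:
    """Expected utilization of the scenario from the arrival/duration model.

    Expected busy rooms is the sum over classes of arrival rate times mean
    occupancy (log-normal mean duration + set-up/clean-up + delta); the
    load factor divides by the time-weighted average staffed room count.
    """
    busy = sum(
        cp.arrival_rate
        * scenario.volume_multiplier
        * (cp.mean_duration + scenario.setup_cleanup_min + scenario.duration_delta_min)
        for cp in params.values()
    )
    staffed = scenario.avg_staffed_rooms
    rho = busy / staffed if staffed > 0 else float("inf")
    return OfferedLoad(
        expected_busy_rooms=busy,
        avg_staffed_rooms=staffed,
        rho=rho,
        stable=rho < 1.0,
    )
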