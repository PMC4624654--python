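"""Analytic multi-server, multi-priority waiting-line model.

The closed-form comparator treats the OR suite as an M/M/s queue with
non-preemptive priority classes (the classic Cobham solution).  Service
time is exponential with mean S, where S is a single pooled mean room
occupancy (surgical time plus set-up/clean-up).  Because surgical
durations are right-skewed, S can be pooled two ways: from the raw mean
duration, or from the back-transformed mean of the log durations; the
latter tracks the Monte Carlo simulation more closely.

With total arrival rate lambda = sum(lambda_k), offered load a = lambda*S
erlangs and rho = a/s, the Erlang-C delay probability P_W gives the
overall mean queueing delay Wq = P_W / (s/S - lambda), which Cobham's
factors split across priority classes:

    B_0 = 1,  B_k = 1 - S * sum_{i<=k} lambda_i / s,
    Wq_k = (1 - rho) * Wq / (B_{k-1} * B_k).

The rate-weighted average of the Wq_k recovers Wq exactly (telescoping).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import ParamsMap, UrgencyClass

__all__ = [
    "erlang_b",
    "erlang_c",
    "mmc_mean_wait",
    "priority_mean_waits",
    "merge_to_four_classes",
    "pooled_mean_service",
]


def erlang_b(s: int, a: float) -> float:
    """Erlang-B blocking probability via the stable recurrence."""
    if s < 1 or s != int(s):
        raise ValueError("server count s must be a positive integer")
    if a < 0:
        raise ValueError("offered load a must be >= 0")
    B = 1.0
    for k in range(1, int(s) + 1):
        B = a * B / (k + a * B)
    return B


def erlang_c(s: int, a: float) -> float:
    """Erlang-C probability that an arriving customer must wait (M/M/s).

    Computed from the Erlang-B recurrence, which is numerically stable
    for any server count (no explicit factorials).
    """
    if a >= s:
        raise ValueError(f"unstable queue: offered load {a} >= servers {s}")
    B = erlang_b(s, a)
    return s * B / (s - a * (1.0 - B))


def mmc_mean_wait(s: int, lambda_total: float, S: float) -> float:
    """Mean M/M/s queueing delay in minutes: Wq = P_W / (s/S - lambda)."""
    if S <= 0:
        raise ValueError("mean service time S must be > 0")
    a = lambda_total * S
    if a >= s:
        raise ValueError(f"unstable queue: lambda*S = {a} >= s = {s}")
    if lambda_total == 0:
        return 0.0
    return erlang_c(s, a) / (s / S - lambda_total)


def priority_mean_waits(
    s: int, lambdas: Sequence[float], S: float
) -> np.ndarray:
    """Per-class mean waits of the non-preemptive M/M/s priority queue.

    ``lambdas`` are ordered highest priority first.  Cobham's formula:
    Wq_k = (1 - rho) * Wq / (B_{k-1} * B_k) with the cumulative factors
    B_k = 1 - S * sum_{i<=k} lambda_i / s.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size < 1 or np.any(lam < 0):
        raise ValueError("need at least one non-negative arrival rate")
    total = float(lam.sum())
    a = total * S
    if a >= s:
        raise ValueError(f"unstable queue: lambda*S = {a} >= s = {s}")
    rho = a / s
    wq = mmc_mean_wait(s, total, S)
    cum = np.cumsum(lam)
    B = np.concatenate([[1.0], 1.0 - cum * S / s])
    return (1.0 - rho) * wq / (B[:-1] * B[1:])


def merge_to_four_classes(params: ParamsMap) -> tuple[float, float, float, float]:
    """Collapse the five classes to four arrival rates for the analytic model.

    Classroom multi-priority solvers commonly cap at four classes, so the
    24-hour urgency class and the add-on elective class are pooled (their
    combined rate, priority last).
    """
    return (
        params[UrgencyClass.EMERGENT].arrival_rate,
        params[UrgencyClass.URGENT1].arrival_rate,
        params[UrgencyClass.URGENT2].arrival_rate,
        params[UrgencyClass.URGENT3].arrival_rate
        + params[UrgencyClass.ADDON].arrival_rate,
    )


def pooled_mean_service(
    params: ParamsMap,
    method: str = "log",
    setup: float = 60.0,
    raw_mean: float | None = None,
) -> float:
    """Pooled mean service (room occupancy) time for the analytic model.

    method="raw" uses a supplied mean of raw surgical durations (they are
    not derivable from the log-scale parameter table alone) plus set-up.
    method="log" back-transforms the rate-weighted mean of the per-class
    log-mean durations, which discounts the right tail, plus set-up.
    """
    if method == "raw":
        if raw_mean is None:
            raise ValueError("method='raw' requires raw_mean")
        return raw_mean + setup
    if method == "log":
        lam = np.array([cp.arrival_rate for cp in params.values()])
        ml = np.array([cp.meanlog for cp in params.values()])
        if lam.sum() == 0:
            raise ValueError("all arrival rates are zero; cannot weight meanlog")
        return float(np.exp(np.average(ml, weights=lam))) + setup
    raise ValueError(f"unknown method {method!r}; use 'raw' or 'log'")
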