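"""Urgency classes, per-class parameters, capacity scenarios and estimation.

The model describes a hospital's non-elective surgical service.  Patients
"arrive" at the minute the decision to operate is made and are sorted into
five urgency classes, from cases that must reach an operating room (OR)
within two hours down to add-on elective cases that can wait days.  Each
class is characterised by a Poisson arrival rate (patients per minute) and
a log-normal surgical-duration distribution parameterised on the natural-log
scale.  A :class:`Scenario` describes the staffed OR capacity: how many
rooms run during the day shift and how many at night, which classes may
start a case at night, and the simulation horizon and burn-in.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MINUTES_PER_YEAR",
    "MINUTES_PER_DAY",
    "UrgencyClass",
    "ClassParams",
    "Scenario",
    "CaseRecord",
    "default_class_params",
    "estimate_class_params",
    "scale_volume",
    "validate_scenario",
]

MINUTES_PER_YEAR = 525_600
MINUTES_PER_DAY = 1_440


class UrgencyClass(enum.IntEnum):
    """The five urgency classes, ordered by clinical priority.

    Lower integer value = higher priority = served first.  EMERGENT cases
    must enter the OR within 2 h; URGENT1 within 0-4-6 h; URGENT2 within
    8-12 h; URGENT3 within 24 h; ADDON is add-on elective (can wait days).
    """

    EMERGENT = 1
    URGENT1 = 2
    URGENT2 = 3
    URGENT3 = 4
    ADDON = 5

    @property
    def priority_rank(self) -> int:
        return int(self)


#: Classes in service-priority order (highest priority first).
PRIORITY_ORDER: tuple[UrgencyClass, ...] = tuple(UrgencyClass)


@dataclass(frozen=True)
class ClassParams:
    """Arrival and duration parameters for one urgency class.

    Parameters
    ----------
    arrival_rate
        Poisson arrival rate in patients per minute.
    meanlog, sdlog
        Mean and standard deviation of the natural log of surgical
        duration in minutes (log-normal model).
    """

    arrival_rate: float
    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise ValueError(f"arrival_rate must be >= 0, got {self.arrival_rate}")
        if self.sdlog < 0:
            raise ValueError(f"sdlog must be >= 0, got {self.sdlog}")
        if not math.isfinite(self.meanlog):
            raise ValueError(f"meanlog must be finite, got {self.meanlog}")

    @property
    def mean_duration(self) -> float:
        """Expected surgical duration in minutes, exp(meanlog + sdlog^2/2)."""
        return math.exp(self.meanlog + 0.5 * self.sdlog**2)

    @property
    def median_duration(self) -> float:
        """Median surgical duration in minutes, exp(meanlog)."""
        return math.exp(self.meanlog)


ParamsMap = Mapping[UrgencyClass, ClassParams]

# Institutional parameter table for ~4800 non-elective cases/year at a
# tertiary academic centre: per-class arrival rates (patients/min) and
# log-normal duration parameters (natural-log minutes).
_DEFAULT_ROWS: dict[UrgencyClass, tuple[float, float, float]] = {
    UrgencyClass.EMERGENT: (0.001607686, 5.00716, 0.583642),
    UrgencyClass.URGENT1: (0.003232496, 4.96477, 0.677607),
    UrgencyClass.URGENT2: (0.002665525, 5.05842, 0.651279),
    UrgencyClass.URGENT3: (0.000334855, 5.00069, 0.570812),
    UrgencyClass.ADDON: (0.001288052, 5.01655, 0.713405),
}


def default_class_params() -> dict[UrgencyClass, ClassParams]:
    """Return the default per-class parameter table.

    These are the published institutional estimates for one year of
    non-elective surgical cases (roughly 4,800 patients/year pooled over
    the five classes).
    """
    return {
        cls: ClassParams(*row) for cls, row in _DEFAULT_ROWS.items()
    }


def scale_volume(params: ParamsMap, multiplier: float) -> dict[UrgencyClass, ClassParams]:
    """Scale every class's arrival rate by ``multiplier``.

    Duration parameters are untouched.  Used for case-volume sensitivity
    analyses (e.g. +5 %, +10 % volume).
    """
    if multiplier <= 0:
        raise ValueError(f"volume multiplier must be > 0, got {multiplier}")
    return {
        cls: replace(cp, arrival_rate=cp.arrival_rate * multiplier)
        for cls, cp in params.items()
    }


@dataclass(frozen=True)
class Scenario:
    """A staffed-capacity scenario for the minute-stepped simulator.

    Attributes
    ----------
    day_or_count, night_or_count
        Rooms staffed during the day window (default 0600-2200) and at
        night (2200-0600).
    day_window
        Half-open ``[start, stop)`` pair of minutes-of-day defining the
        day shift; default ``(360, 1320)``, i.e. 16 hours.
    setup_cleanup_min
        Constant added to every case's room occupancy for pre-op set-up
        plus post-op clean-up.
    duration_delta_min
        Signed minutes added to each room occupancy (sensitivity knob for
        longer/shorter surgery or turnover); occupancy is floored at 1 min.
    volume_multiplier
        Dimensionless scale applied to all arrival rates at run time.
    night_eligible_classes
        Urgency classes allowed to *start* a case during night minutes.
        Running cases always continue across shift changes.
    horizon_min, burnin_min
        Total simulated minutes (default 5 years) and the leading warm-up
        period excluded from statistics (default 2 months = 87,600 min).
    n_runs, base_seed
        Replicate count and the seed of the first replicate (replicate i
        uses ``base_seed + i``).
    """

    day_or_count: int
    night_or_count: int
    day_window: tuple[int, int] = (360, 1320)
    setup_cleanup_min: int = 60
    duration_delta_min: int = 0
    volume_multiplier: float = 1.0
    night_eligible_classes: frozenset[UrgencyClass] = frozenset(UrgencyClass)
    horizon_min: int = 5 * MINUTES_PER_YEAR
    burnin_min: int = 87_600
    n_runs: int = 4
    base_seed: int = 0

    def cap_at(self, minute: int) -> int:
        """Staffed room count at an absolute simulation minute."""
        m = minute % MINUTES_PER_DAY
        lo, hi = self.day_window
        return self.day_or_count if lo <= m < hi else self.night_or_count

    def is_day(self, minute: int) -> bool:
        m = minute % MINUTES_PER_DAY
        lo, hi = self.day_window
        return lo <= m < hi

    @property
    def avg_staffed_rooms(self) -> float:
        """Time-weighted average staffed room count over a day."""
        lo, hi = self.day_window
        day_len = hi - lo
        return (
            self.day_or_count * day_len
            + self.night_or_count * (MINUTES_PER_DAY - day_len)
        ) / MINUTES_PER_DAY


def validate_scenario(scenario: Scenario) -> list[str]:
    """Check scenario invariants; return a list of violations (empty if OK)."""
    v: list[str] = []
    if scenario.day_or_count < 0:
        v.append("day_or_count: must be >= 0")
    if scenario.night_or_count < 0:
        v.append("night_or_count: must be >= 0")
    lo, hi = scenario.day_window
    if not (0 <= lo < hi <= MINUTES_PER_DAY):
        v.append("day_window: must satisfy 0 <= start < stop <= 1440")
    if scenario.burnin_min >= scenario.horizon_min:
        v.append("burnin_min: must be strictly less than horizon_min")
    if scenario.burnin_min < 0:
        v.append("burnin_min: must be >= 0")
    if scenario.volume_multiplier <= 0:
        v.append("volume_multiplier: must be > 0")
    if UrgencyClass.EMERGENT not in scenario.night_eligible_classes:
        v.append("night_eligible_classes: must always contain EMERGENT")
    if scenario.n_runs < 1:
        v.append("n_runs: must be >= 1")
    if scenario.setup_cleanup_min < 0:
        v.append("setup_cleanup_min: must be >= 0")
    return v


@dataclass(frozen=True)
class CaseRecord:
    """One raw case-log row: urgency plus the three administrative times.

    ``request_time`` is when the schedule request was submitted (the
    arrival in queueing terms); ``wheels_in``/``wheels_out`` bracket the
    room occupancy used to measure surgical duration.
    """

    urgency: UrgencyClass
    request_time: datetime
    wheels_in: datetime
    wheels_out: datetime

    def __post_init__(self) -> None:
        if self.wheels_out <= self.wheels_in:
            raise ValueError("wheels_out must be after wheels_in")
        if self.request_time > self.wheels_in:
            raise ValueError("request_time must not be after wheels_in")

    def duration_minutes(self) -> int:
        """Surgical duration in whole minutes (timestamps truncated to minutes)."""
        t_in = self.wheels_in.replace(second=0, microsecond=0)
        t_out = self.wheels_out.replace(second=0, microsecond=0)
        return int((t_out - t_in).total_seconds() // 60)


def estimate_class_params(
    records: Iterable[CaseRecord],
    observation_minutes: float,
) -> dict[UrgencyClass, ClassParams]:
    """Estimate per-class parameters from raw case-log records.

    Arrival rate is the class's record count divided by
    ``observation_minutes``.  Duration parameters are the mean and sample
    (n-1) standard deviation of the natural log of wheels-in-to-wheels-out
    durations in minutes.  Records with a non-positive duration are
    dropped with a warning; a class with no usable records raises.
    """
    if observation_minutes <= 0:
        raise ValueError("observation_minutes must be > 0")
    logs: dict[UrgencyClass, list[float]] = {cls: [] for cls in UrgencyClass}
    for rec in records:
        dur = rec.duration_minutes()
        if dur <= 0:
            warnings.warn(
                f"dropping {rec.urgency.name} record with non-positive "
                f"duration ({dur} min)",
                stacklevel=2,
            )
            continue
        logs[rec.urgency].append(math.log(dur))
    out: dict[UrgencyClass, ClassParams] = {}
    for cls in UrgencyClass:
        vals = logs[cls]
        if not vals:
            raise ValueError(f"no usable records for class {cls.name}")
        arr = np.asarray(vals)
        sdlog = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
        out[cls] = ClassParams(
            arrival_rate=len(vals) / observation_minutes,
            meanlog=float(arr.mean()),
            sdlog=sdlog,
        )
    return out
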