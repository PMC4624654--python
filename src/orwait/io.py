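"""Case-log CSV I/O, config files, fixture generation and table output.

The case-log format is one row per surgical case:

    urgency,request_time,wheels_in,wheels_out

with ISO-8601 timestamps and urgency one of EMERGENT, URGENT1, URGENT2,
URGENT3, ADDON.  Config files are YAML with two top-level keys,
``scenario`` and ``classes``; unknown keys are rejected so typos fail
loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .config import (
    CaseRecord,
    ClassParams,
    ParamsMap,
    Scenario,
    UrgencyClass,
)
from .engine import SimResult, draw_arrival_counts, lognormal_duration_sampler
from .stats import RunAggregate, STATISTICS

__all__ = [
    "CaseLogError",
    "CASELOG_HEADER",
    "read_case_records",
    "write_case_records",
    "generate_fixture_log",
    "write_patient_csv",
    "write_summary_csv",
    "write_table_csv",
    "load_config",
    "dump_config",
    "config_hash",
]

CASELOG_HEADER = ["urgency", "request_time", "wheels_in", "wheels_out"]


class CaseLogError(ValueError):
    """Malformed case-log input, with the offending line number."""


def _parse_ts(text: str, line_no: int, col: str) -> datetime:
    try:
        return datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise CaseLogError(
            f"line {line_no}: bad {col} timestamp {text!r}: {exc}"
        ) from None


def read_case_records(path: str | Path) -> list[CaseRecord]:
    """Strictly parse a case-log CSV; raise with line numbers on bad rows."""
    path = Path(path)
    records: list[CaseRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CaseLogError("empty file: missing header") from None
        if [h.strip() for h in header] != CASELOG_HEADER:
            raise CaseLogError(
                f"line 1: expected header {','.join(CASELOG_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise CaseLogError(
                    f"line {line_no}: expected 4 columns, got {len(row)}"
                )
            label = row[0].strip()
            try:
                urgency = UrgencyClass[label]
            except KeyError:
                raise CaseLogError(
                    f"line {line_no}: unknown urgency class {label!r}"
                ) from None
            request = _parse_ts(row[1], line_no, "request_time")
            w_in = _parse_ts(row[2], line_no, "wheels_in")
            w_out = _parse_ts(row[3], line_no, "wheels_out")
            try:
                records.append(
                    CaseRecord(
                        urgency=urgency,
                        request_time=request,
                        wheels_in=w_in,
                        wheels_out=w_out,
                    )
                )
            except ValueError as exc:
                raise CaseLogError(f"line {line_no}: {exc}") from None
    if not records:
        warnings.warn(f"{path}: case log contains a header but no records",
                      stacklevel=2)
    return records


def write_case_records(records: Sequence[CaseRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CASELOG_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.urgency.name,
                    rec.request_time.isoformat(),
                    rec.wheels_in.isoformat(),
                    rec.wheels_out.isoformat(),
                ]
            )


def generate_fixture_log(
    params: ParamsMap,
    minutes: int,
    seed: int | None = None,
    start: datetime = datetime(2013, 1, 1),
) -> list[CaseRecord]:
    """Synthetic case log: Poisson arrivals, log-normal durations per class.

    Emulates one observation window of an institution's administrative
    data at minute resolution; wheels-in equals the request minute and
    durations are truncated to whole minutes (minimum 1), so the log
    round-trips through parameter estimation.
    """
    if minutes <= 0:
        raise ValueError("minutes must be > 0")
    rng = np.random.default_rng(seed)
    records: list[CaseRecord] = []
    for cls in UrgencyClass:
        cp = params[cls]
        counts = draw_arrival_counts(cp.arrival_rate, minutes, rng)
        idx = np.nonzero(counts)[0]
        mins = np.repeat(idx, counts[idx])
        durs = np.maximum(
            lognormal_duration_sampler(cp, mins.size, rng).astype(np.int64), 1
        )
        for m, d in zip(mins, durs):
            t0 = start + timedelta(minutes=int(m))
            records.append(
                CaseRecord(
                    urgency=cls,
                    request_time=t0,
                    wheels_in=t0,
                    wheels_out=t0 + timedelta(minutes=int(d)),
                )
            )
    records.sort(key=lambda r: (r.request_time, r.urgency))
    return records


def write_patient_csv(results: Sequence[SimResult], path: str | Path) -> None:
    """Per-patient output, one row per simulated case across all runs.

    Pending patients (no room by the horizon) have empty start/wait.
    """
    import pandas as pd

    frames = [res.to_frame(run=i) for i, res in enumerate(results)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summary_csv(
    aggregates: dict[str, RunAggregate] | RunAggregate, path: str | Path
) -> None:
    """Machine-readable long format: scenario,class,statistic,mean,sd."""
    if isinstance(aggregates, RunAggregate):
        aggregates = {"scenario": aggregates}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scenario", "class", "statistic", "mean", "sd"])
        for name, agg in aggregates.items():
            for cls in UrgencyClass:
                if cls not in agg.per_class:
                    continue
                for stat in STATISTICS:
                    m, s = agg.per_class[cls][stat]
                    writer.writerow([name, cls.name, stat, f"{m:.6g}", f"{s:.6g}"])
            m, s = agg.utilization_pct
            writer.writerow([name, "ALL", "utilization_pct", f"{m:.6g}", f"{s:.6g}"])


def write_table_csv(
    aggregates: dict[str, RunAggregate], path: str | Path, digits: int = 0
) -> None:
    """Human-readable table: rows class x statistic, cells "mean +/- SD"."""
    names = list(aggregates)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "statistic", *names])
        for cls in UrgencyClass:
            for stat in ("mean", "median", "p95"):
                row = [cls.name, stat]
                for name in names:
                    agg = aggregates[name]
                    if cls not in agg.per_class:
                        row.append("")
                        continue
                    m, s = agg.per_class[cls][stat]
                    row.append(f"{m:.{digits}f} ± {s:.{digits}f}")
                writer.writerow(row)
        row = ["ALL", "utilization_pct"]
        for name in names:
            m, s = aggregates[name].utilization_pct
            row.append(f"{m:.1f} ± {s:.1f}")
        writer.writerow(row)


# ---------------------------------------------------------------------------
# Config files

_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(Scenario)}
_CLASS_FIELDS = {f.name for f in dataclasses.fields(ClassParams)}


def _scenario_to_dict(scenario: Scenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["day_window"] = list(scenario.day_window)
    d["night_eligible_classes"] = sorted(
        cls.name for cls in scenario.night_eligible_classes
    )
    return d


def dump_config(scenario: Scenario, params: ParamsMap, path: str | Path) -> None:
    doc = {
        "scenario": _scenario_to_dict(scenario),
        "classes": {
            cls.name: {
                "arrival_rate": params[cls].arrival_rate,
                "meanlog": params[cls].meanlog,
                "sdlog": params[cls].sdlog,
            }
            for cls in UrgencyClass
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[Scenario, dict[UrgencyClass, ClassParams]]:
    """Load a scenario + class-parameter config; unknown keys are errors."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    unknown = set(doc) - {"scenario", "classes"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    sdoc = dict(doc.get("scenario", {}))
    unknown = set(sdoc) - _SCENARIO_FIELDS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "day_window" in sdoc:
        sdoc["day_window"] = tuple(sdoc["day_window"])
    if "night_eligible_classes" in sdoc:
        sdoc["night_eligible_classes"] = frozenset(
            UrgencyClass[name] for name in sdoc["night_eligible_classes"]
        )
    scenario = Scenario(**sdoc)
    cdoc = doc.get("classes", {})
    unknown = set(cdoc) - {cls.name for cls in UrgencyClass}
    if unknown:
        raise ValueError(f"unknown urgency classes in config: {sorted(unknown)}")
    from .config import default_class_params

    params = default_class_params()
    for name, fields in cdoc.items():
        extra = set(fields) - _CLASS_FIELDS
        if extra:
            raise ValueError(f"unknown class-parameter keys for {name}: {sorted(extra)}")
        params[UrgencyClass[name]] = ClassParams(**fields)
    return scenario, params


def config_hash(scenario: Scenario, params: ParamsMap) -> str:
    """Short stable digest of the full configuration, for provenance logs."""
    doc = {
        "scenario": _scenario_to_dict(scenario),
        "classes": {
            cls.name: dataclasses.asdict(params[cls]) for cls in UrgencyClass
        },
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
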