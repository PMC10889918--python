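"""MAP trace data model, cohort CSV I/O and study inclusion filtering.

The unit of analysis throughout the package is the trend-level mean
arterial pressure (MAP) sample as exported by a hemodynamic monitoring
platform: one value every ``nominal_interval`` seconds (default 20 s),
per patient, for the duration of intraoperative monitoring.  A cohort is
a collection of such traces plus a per-patient metadata table carrying
the variables the inclusion/exclusion screen needs (age, elective
status, surgery duration, cardiac exclusion flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

TRACE_COLUMNS = ("patient_id", "group", "time_s", "map_mmhg")
META_COLUMNS = (
    "patient_id",
    "group",
    "age_years",
    "surgery_duration_min",
    "elective",
    "arrhythmia_flag",
    "ef_below_35_flag",
    "severe_stenosis_flag",
)

#: Default plausibility window for trend MAP values (mmHg).  Values
#: outside it at load time are treated as artifacts and rejected.
DEFAULT_MAP_BOUNDS = (10.0, 200.0)


@dataclass(frozen=True)
class MapTrace:
    """One patient's timestamped MAP series.

    Parameters
    ----------
    patient_id : str
        Opaque identifier; unique within a cohort.
    group : str
        Monitoring-arm label (e.g. ``"FloTrac"`` or ``"HPI"``).
    times : ndarray of float
        Sample times in seconds from monitoring start; strictly
        increasing, finite, non-negative.
    map_values : ndarray of float
        MAP in mmHg, aligned with ``times``.
    nominal_interval : float
        Nominal sampling interval of the monitor export in seconds.
        Irregular sampling is permitted; all integrals use the actual
        timestamps, the nominal interval only bounds per-sample coverage
        around gaps.
    """

    patient_id: str
    group: str
    times: np.ndarray
    map_values: np.ndarray
    nominal_interval: float = 20.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        maps = np.asarray(self.map_values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "map_values", maps)
        if times.ndim != 1 or maps.ndim != 1:
            raise ValidationError("times and map_values must be 1-D")
        if len(times) != len(maps):
            raise ValidationError(
                f"patient {self.patient_id}: {len(times)} times vs "
                f"{len(maps)} MAP values"
            )
        if len(times) == 0:
            raise ValidationError(f"patient {self.patient_id}: empty trace")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(maps)):
            raise ValidationError(f"patient {self.patient_id}: non-finite data")
        if times[0] < 0:
            raise ValidationError(f"patient {self.patient_id}: negative time")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"patient {self.patient_id}: times not strictly increasing"
            )
        if self.nominal_interval <= 0:
            raise ValidationError("nominal_interval must be positive")

    @property
    def monitoring_min(self) -> float:
        """Total monitoring duration, last minus first timestamp, minutes."""
        return float(self.times[-1] - self.times[0]) / 60.0

    def equals(self, other: "MapTrace") -> bool:
        return (
            self.patient_id == other.patient_id
            and self.group == other.group
            and self.nominal_interval == other.nominal_interval
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.map_values, other.map_values)
        )


@dataclass(frozen=True)
class PatientMeta:
    """Per-patient screening metadata for the inclusion/exclusion filter."""

    patient_id: str
    group: str
    age_years: int
    surgery_duration_min: float
    elective: bool = True
    arrhythmia_flag: bool = False
    ef_below_35_flag: bool = False
    severe_stenosis_flag: bool = False

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValidationError(f"patient {self.patient_id}: age must be > 0")
        if self.surgery_duration_min <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: surgery duration must be > 0"
            )


@dataclass
class CohortTable:
    """Ordered collection of traces and metadata keyed by patient id."""

    traces: dict[str, MapTrace] = field(default_factory=dict)
    meta: dict[str, PatientMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.traces) != set(self.meta):
            only_t = set(self.traces) - set(self.meta)
            only_m = set(self.meta) - set(self.traces)
            raise ValidationError(
                "trace/metadata mismatch: traces without meta "
                f"{sorted(only_t)}, meta without trace {sorted(only_m)}"
            )
        for pid, trace in self.traces.items():
            if trace.group != self.meta[pid].group:
                raise ValidationError(
                    f"patient {pid}: group differs between trace "
                    f"({trace.group}) and metadata ({self.meta[pid].group})"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[MapTrace]:
        return iter(self.traces.values())

    @property
    def patient_ids(self) -> list[str]:
        return list(self.traces)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for t in self.traces.values():
            if t.group not in seen:
                seen.append(t.group)
        return seen

    def subset(self, patient_ids: Sequence[str]) -> "CohortTable":
        keep = [pid for pid in self.traces if pid in set(patient_ids)]
        return CohortTable(
            traces={pid: self.traces[pid] for pid in keep},
            meta={pid: self.meta[pid] for pid in keep},
        )

    def equals(self, other: "CohortTable") -> bool:
        if list(self.traces) != list(other.traces):
            return False
        return all(
            self.traces[p].equals(other.traces[p]) and self.meta[p] == other.meta[p]
            for p in self.traces
        )


def _parse_bool_column(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise ParseError(f"column {column!r}, row {row}: not a boolean")
    return out.astype(bool)


def _parse_numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise ParseError(f"column {column!r}, row {row}: not numeric")
    return out


def read_cohort_csv(
    trace_path,
    meta_path,
    map_bounds: tuple[float, float] = DEFAULT_MAP_BOUNDS,
    nominal_interval: float = 20.0,
    artifact_policy: str = "reject",
) -> CohortTable:
    """Read a cohort from long-format trace and metadata CSV files.

    The trace file needs columns ``patient_id, group, time_s, map_mmhg``;
    rows need not be sorted.  MAP values outside ``map_bounds`` raise a
    :class:`ValidationError` naming the offending row unless
    ``artifact_policy="allow"``.
    """
    trace_df = pd.read_csv(trace_path, float_precision="round_trip")
    meta_df = pd.read_csv(meta_path, float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in trace_df.columns:
            raise SchemaError(f"trace file missing column {col!r}")
    for col in META_COLUMNS:
        if col not in meta_df.columns:
            raise SchemaError(f"metadata file missing column {col!r}")

    if len(trace_df):
        trace_df["time_s"] = _parse_numeric(trace_df["time_s"], "time_s")
        trace_df["map_mmhg"] = _parse_numeric(trace_df["map_mmhg"], "map_mmhg")
        trace_df["patient_id"] = trace_df["patient_id"].astype(str)
        dup = trace_df.duplicated(subset=["patient_id", "time_s"])
        if dup.any():
            row = int(trace_df.index[dup][0])
            raise ValidationError(f"duplicate (patient_id, time_s) at row {row}")
        if artifact_policy == "reject":
            lo, hi = map_bounds
            bad = (trace_df["map_mmhg"] < lo) | (trace_df["map_mmhg"] > hi)
            if bad.any():
                row = int(trace_df.index[bad][0])
                raise ValidationError(
                    f"row {row}: MAP {trace_df.loc[row, 'map_mmhg']:g} mmHg "
                    f"outside plausibility window [{lo:g}, {hi:g}]"
                )
    meta_df["patient_id"] = meta_df["patient_id"].astype(str)
    if meta_df["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in metadata file")

    meta: dict[str, PatientMeta] = {}
    if len(meta_df):
        meta_df["age_years"] = _parse_numeric(meta_df["age_years"], "age_years")
        meta_df["surgery_duration_min"] = _parse_numeric(
            meta_df["surgery_duration_min"], "surgery_duration_min"
        )
        for col in ("elective", "arrhythmia_flag", "ef_below_35_flag", "severe_stenosis_flag"):
            meta_df[col] = _parse_bool_column(meta_df[col], col)
    for _, row in meta_df.iterrows():
        meta[row["patient_id"]] = PatientMeta(
            patient_id=row["patient_id"],
            group=str(row["group"]),
            age_years=int(row["age_years"]),
            surgery_duration_min=float(row["surgery_duration_min"]),
            elective=bool(row["elective"]),
            arrhythmia_flag=bool(row["arrhythmia_flag"]),
            ef_below_35_flag=bool(row["ef_below_35_flag"]),
            severe_stenosis_flag=bool(row["severe_stenosis_flag"]),
        )

    traces: dict[str, MapTrace] = {}
    if len(trace_df):
        for pid, sub in trace_df.groupby("patient_id", sort=False):
            groups = sub["group"].astype(str).unique()
            if len(groups) > 1:
                raise ValidationError(
                    f"patient {pid}: conflicting group labels {sorted(groups)}"
                )
            sub = sub.sort_values("time_s")
            traces[str(pid)] = MapTrace(
                patient_id=str(pid),
                group=str(groups[0]),
                times=sub["time_s"].to_numpy(dtype=float),
                map_values=sub["map_mmhg"].to_numpy(dtype=float),
                nominal_interval=nominal_interval,
            )
    # keep metadata-file patient order where possible
    ordered = {pid: traces[pid] for pid in meta if pid in traces}
    ordered.update(traces)
    return CohortTable(traces=ordered, meta=meta)


def write_cohort_csv(cohort: CohortTable, trace_path, meta_path) -> None:
    """Write a cohort so that :func:`read_cohort_csv` reproduces it exactly.

    Floats are written with Python ``repr`` precision, which round-trips
    IEEE doubles bit-exactly.
    """
    trace_rows = []
    for trace in cohort:
        for t, m in zip(trace.times, trace.map_values):
            trace_rows.append((trace.patient_id, trace.group, repr(float(t)), repr(float(m))))
    trace_df = pd.DataFrame(trace_rows, columns=list(TRACE_COLUMNS))
    trace_df.to_csv(trace_path, index=False)

    meta_rows = []
    for pid in cohort.patient_ids:
        m = cohort.meta[pid]
        meta_rows.append(
            (
                m.patient_id,
                m.group,
                m.age_years,
                repr(float(m.surgery_duration_min)),
                str(m.elective).lower(),
                str(m.arrhythmia_flag).lower(),
                str(m.ef_below_35_flag).lower(),
                str(m.severe_stenosis_flag).lower(),
            )
        )
    meta_df = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    meta_df.to_csv(meta_path, index=False)


@dataclass(frozen=True)
class Exclusion:
    """One removed patient and the first screening rule they violated."""

    patient_id: str
    rule: str


def apply_inclusion_filters(
    cohort: CohortTable,
    min_duration_min: float = 120.0,
    min_age: int = 18,
) -> tuple[CohortTable, list[Exclusion]]:
    """Apply the study's inclusion/exclusion screen.

    Retains patients who are adults (age >= ``min_age``; the boundary age
    itself is included, since the exclusion rule is "age < 18"), had
    elective surgery lasting strictly more than ``min_duration_min``
    minutes, and carry none of the cardiac exclusion flags (arrhythmia
    impairing the pressure waveform, ejection fraction < 35 %, severe
    aortic/mitral stenosis).  Rules are checked in a fixed order and the
    report records the first violated rule per excluded patient.
    """
    kept: list[str] = []
    excluded: list[Exclusion] = []
    for pid in cohort.patient_ids:
        m = cohort.meta[pid]
        if m.age_years < min_age:
            excluded.append(Exclusion(pid, "age_below_minimum"))
        elif not (m.surgery_duration_min > min_duration_min):
            excluded.append(Exclusion(pid, "surgery_duration_not_above_minimum"))
        elif not m.elective:
            excluded.append(Exclusion(pid, "non_elective_surgery"))
        elif m.arrhythmia_flag:
            excluded.append(Exclusion(pid, "arrhythmia"))
        elif m.ef_below_35_flag:
            excluded.append(Exclusion(pid, "ejection_fraction_below_35"))
        elif m.severe_stenosis_flag:
            excluded.append(Exclusion(pid, "severe_valvular_stenosis"))
        else:
            kept.append(pid)
    return cohort.subset(kept), excluded
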