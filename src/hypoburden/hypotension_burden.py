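"""Hypotensive-event detection and burden endpoints on MAP trend data.

A hypotensive event is a maximal contiguous run of MAP samples strictly
below a threshold (65 mmHg for ordinary, 50 mmHg for severe hypotension)
lasting strictly more than a minimum duration (default one minute).  The
primary burden endpoint is the time-weighted average (TWA) of
hypotension::

    TWA = (depth below threshold [mmHg] x time below threshold [min])
          / total monitoring duration [min]

i.e. the area between the threshold and the MAP curve while below it,
normalised by monitoring time; units mmHg.  Secondary endpoints are the
event count, cumulative and average event duration, and time below
threshold as a percentage of monitoring time, per patient and threshold.

Sampling semantics
------------------
The data are trend samples, so sub-sample crossing times are unknowable:
each sample covers the half-open interval from its own timestamp to the
next one (no interpolation), and the last sample of a trace covers
nothing.  Area uses the rectangle rule over sub-threshold samples.  A
gap longer than ``gap_factor`` nominal intervals caps the preceding
sample's coverage at one nominal interval and terminates any running
event; by default the gap interior counts as above-threshold time and
the monitoring denominator stays wall-clock (last minus first
timestamp), with a stricter policy that removes gap excess from the
denominator as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .trace_core import CohortTable, MapTrace

STUDY_THRESHOLDS = (65.0, 50.0)


@dataclass(frozen=True)
class EventConfig:
    """Event definition and TWA accounting options.

    ``twa_scope`` selects what the TWA numerator integrates:
    ``"qualifying_events_only"`` counts only area inside events longer
    than ``min_duration_s`` (consistent with the event definition);
    ``"all_subthreshold_time"`` counts every sub-threshold sample,
    including sub-minute excursions.
    """

    threshold_mmhg: float = 65.0
    min_duration_s: float = 60.0
    twa_scope: str = "qualifying_events_only"
    gap_policy: str = "wall_clock"  # or "exclude_gaps"
    gap_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_mmhg <= 0:
            raise ConfigError("threshold must be positive")
        if self.min_duration_s < 0:
            raise ConfigError("min_duration_s must be >= 0")
        if self.twa_scope not in ("qualifying_events_only", "all_subthreshold_time"):
            raise ConfigError(f"unknown twa_scope {self.twa_scope!r}")
        if self.gap_policy not in ("wall_clock", "exclude_gaps"):
            raise ConfigError(f"unknown gap_policy {self.gap_policy!r}")


@dataclass(frozen=True)
class HypotensionEvent:
    """A contiguous sub-threshold episode."""

    threshold_mmhg: float
    start_s: float
    end_s: float
    duration_min: float
    area_mmhg_min: float
    nadir_mmhg: float


@dataclass(frozen=True)
class ThresholdBurden:
    """Per-patient burden metrics at one MAP threshold."""

    threshold_mmhg: float
    n_events: int
    total_time_below_min: float
    mean_event_duration_min: float
    median_event_duration_min: float
    twa_mmhg: float
    pct_time_below: float
    any_event: bool
    event_durations_min: tuple[float, ...] = ()


@dataclass(frozen=True)
class PatientBurden:
    """All burden endpoints for one patient across the study thresholds."""

    patient_id: str
    group: str
    monitoring_min: float
    per_threshold: dict[float, ThresholdBurden] = field(default_factory=dict)

    def at(self, threshold: float) -> ThresholdBurden:
        return self.per_threshold[float(threshold)]


def _coverage(trace: MapTrace, cfg: EventConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample time coverage (s) and gap-after-sample flags."""
    dt = np.diff(trace.times)
    gap = dt > cfg.gap_factor * trace.nominal_interval
    cov = np.where(gap, trace.nominal_interval, dt)
    cov = np.append(cov, 0.0)  # last sample covers nothing
    gap_after = np.append(gap, False)
    return cov, gap_after


def monitoring_duration_min(trace: MapTrace, cfg: EventConfig) -> float:
    """Monitoring denominator in minutes under the configured gap policy."""
    if cfg.gap_policy == "wall_clock":
        return trace.monitoring_min
    cov, _ = _coverage(trace, cfg)
    return float(cov.sum()) / 60.0


def detect_events(trace: MapTrace, cfg: EventConfig) -> list[HypotensionEvent]:
    """Find qualifying hypotensive events in a trace.

    Returns disjoint, time-ordered maximal runs of samples with MAP
    strictly below ``cfg.threshold_mmhg`` whose covered duration exceeds
    ``cfg.min_duration_s`` (strict).  Area is the rectangle-rule sum of
    (threshold - MAP) x coverage over the run's samples, in mmHg.min.
    """
    if len(trace.times) < 2:
        raise ValidationError(
            f"patient {trace.patient_id}: need at least 2 samples to detect events"
        )
    below = trace.map_values < cfg.threshold_mmhg
    cov, gap_after = _coverage(trace, cfg)
    events: list[HypotensionEvent] = []
    n = len(below)
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1] and not gap_after[j]:
            j += 1
        run_cov = cov[i : j + 1]
        duration_s = float(run_cov.sum())
        if duration_s > cfg.min_duration_s:
            depth = cfg.threshold_mmhg - trace.map_values[i : j + 1]
            events.append(
                HypotensionEvent(
                    threshold_mmhg=cfg.threshold_mmhg,
                    start_s=float(trace.times[i]),
                    end_s=float(trace.times[i] + duration_s),
                    duration_min=duration_s / 60.0,
                    area_mmhg_min=float(np.sum(depth * run_cov)) / 60.0,
                    nadir_mmhg=float(trace.map_values[i : j + 1].min()),
                )
            )
        i = j + 1
    return events


def subthreshold_area_time(
    trace: MapTrace, cfg: EventConfig
) -> tuple[float, float]:
    """Total area (mmHg.min) and time (min) below threshold, all samples."""
    cov, _ = _coverage(trace, cfg)
    depth = np.maximum(0.0, cfg.threshold_mmhg - trace.map_values)
    below = trace.map_values < cfg.threshold_mmhg
    area = float(np.sum(depth * cov)) / 60.0
    time_below = float(np.sum(cov[below])) / 60.0
    return area, time_below


def compute_twa(
    trace: MapTrace, events: Sequence[HypotensionEvent], cfg: EventConfig
) -> float:
    """Time-weighted average of hypotension for one trace, in mmHg.

    Numerator scope follows ``cfg.twa_scope``; the denominator is the
    monitoring duration under ``cfg.gap_policy``.
    """
    denom_min = monitoring_duration_min(trace, cfg)
    if denom_min <= 0:
        raise ValidationError(
            f"patient {trace.patient_id}: zero monitoring duration"
        )
    if cfg.twa_scope == "qualifying_events_only":
        numerator = float(sum(e.area_mmhg_min for e in events))
    else:
        numerator, _ = subthreshold_area_time(trace, cfg)
    return numerator / denom_min


def patient_burden(
    trace: MapTrace,
    thresholds: Iterable[float] = STUDY_THRESHOLDS,
    cfg: EventConfig = EventConfig(),
) -> PatientBurden:
    """Assemble all per-patient burden endpoints for each threshold.

    ``cfg`` acts as a template: its threshold is replaced by each entry
    of ``thresholds`` in turn.
    """
    per: dict[float, ThresholdBurden] = {}
    monitoring = monitoring_duration_min(trace, cfg)
    for thr in thresholds:
        tcfg = EventConfig(
            threshold_mmhg=float(thr),
            min_duration_s=cfg.min_duration_s,
            twa_scope=cfg.twa_scope,
            gap_policy=cfg.gap_policy,
            gap_factor=cfg.gap_factor,
        )
        events = detect_events(trace, tcfg)
        durations = tuple(e.duration_min for e in events)
        if tcfg.twa_scope == "qualifying_events_only":
            total_time = float(sum(durations))
        else:
            _, total_time = subthreshold_area_time(trace, tcfg)
        twa = compute_twa(trace, events, tcfg)
        per[float(thr)] = ThresholdBurden(
            threshold_mmhg=float(thr),
            n_events=len(events),
            total_time_below_min=total_time,
            mean_event_duration_min=float(np.mean(durations)) if durations else 0.0,
            median_event_duration_min=float(np.median(durations)) if durations else 0.0,
            twa_mmhg=twa,
            pct_time_below=100.0 * total_time / monitoring if monitoring > 0 else 0.0,
            any_event=bool(events),
            event_durations_min=durations,
        )
    return PatientBurden(
        patient_id=trace.patient_id,
        group=trace.group,
        monitoring_min=monitoring,
        per_threshold=per,
    )


def cohort_burden(
    cohort: CohortTable,
    thresholds: Iterable[float] = STUDY_THRESHOLDS,
    cfg: EventConfig = EventConfig(),
) -> list[PatientBurden]:
    """Per-patient burden for every trace in a cohort, in cohort order."""
    thresholds = tuple(thresholds)
    return [patient_burden(t, thresholds, cfg) for t in cohort]


def _thr_key(thr: float) -> str:
    return f"{thr:g}"


def burden_frame(burdens: Sequence[PatientBurden]) -> pd.DataFrame:
    """Flatten burdens to one row per patient (columns suffixed _<thr>)."""
    rows = []
    for b in burdens:
        row: dict[str, object] = {
            "patient_id": b.patient_id,
            "group": b.group,
            "monitoring_min": b.monitoring_min,
        }
        for thr, tb in b.per_threshold.items():
            k = _thr_key(thr)
            row[f"n_events_{k}"] = tb.n_events
            row[f"total_time_below_min_{k}"] = tb.total_time_below_min
            row[f"mean_event_duration_min_{k}"] = tb.mean_event_duration_min
            row[f"median_event_duration_min_{k}"] = tb.median_event_duration_min
            row[f"twa_mmhg_{k}"] = tb.twa_mmhg
            row[f"pct_time_below_{k}"] = tb.pct_time_below
            row[f"any_event_{k}"] = tb.any_event
        rows.append(row)
    return pd.DataFrame(rows)


def events_frame(
    cohort: CohortTable,
    thresholds: Iterable[float] = STUDY_THRESHOLDS,
    cfg: EventConfig = EventConfig(),
) -> pd.DataFrame:
    """One row per detected event across the cohort and thresholds."""
    rows = []
    for trace in cohort:
        for thr in thresholds:
            tcfg = EventConfig(
                threshold_mmhg=float(thr),
                min_duration_s=cfg.min_duration_s,
                twa_scope=cfg.twa_scope,
                gap_policy=cfg.gap_policy,
                gap_factor=cfg.gap_factor,
            )
            for e in detect_events(trace, tcfg):
                rows.append(
                    {
                        "patient_id": trace.patient_id,
                        "group": trace.group,
                        "threshold_mmhg": e.threshold_mmhg,
                        "start_s": e.start_s,
                        "end_s": e.end_s,
                        "duration_min": e.duration_min,
                        "area_mmhg_min": e.area_mmhg_min,
                        "nadir_mmhg": e.nadir_mmhg,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "group",
            "threshold_mmhg",
            "start_s",
            "end_s",
            "duration_min",
            "area_mmhg_min",
            "nadir_mmhg",
        ],
    )


def burdens_from_frames(
    burden_df: pd.DataFrame, events_df: pd.DataFrame
) -> list[PatientBurden]:
    """Rebuild :class:`PatientBurden` objects from the two CSV tables."""
    thresholds = sorted(
        {
            float(c.rsplit("_", 1)[1])
            for c in burden_df.columns
            if c.startswith("twa_mmhg_")
        },
        reverse=True,
    )
    out = []
    for _, row in burden_df.iterrows():
        pid = str(row["patient_id"])
        per = {}
        for thr in thresholds:
            k = _thr_key(thr)
            if len(events_df):
                mask = (events_df["patient_id"].astype(str) == pid) & (
                    events_df["threshold_mmhg"] == thr
                )
                durations = tuple(events_df.loc[mask, "duration_min"].astype(float))
            else:
                durations = ()
            per[thr] = ThresholdBurden(
                threshold_mmhg=thr,
                n_events=int(row[f"n_events_{k}"]),
                total_time_below_min=float(row[f"total_time_below_min_{k}"]),
                mean_event_duration_min=float(row[f"mean_event_duration_min_{k}"]),
                median_event_duration_min=float(row[f"median_event_duration_min_{k}"]),
                twa_mmhg=float(row[f"twa_mmhg_{k}"]),
                pct_time_below=float(row[f"pct_time_below_{k}"]),
                any_event=bool(row[f"any_event_{k}"]),
                event_durations_min=durations,
            )
        out.append(
            PatientBurden(
                patient_id=pid,
                group=str(row["group"]),
                monitoring_min=float(row["monitoring_min"]),
                per_threshold=per,
            )
        )
    return out
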