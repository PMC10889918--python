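"""Shared fixtures: hand-built traces and small synthetic cohorts."""

import numpy as np
import pytest

from hypoburden import CohortTable, MapTrace, PatientMeta


def make_trace(
    map_values,
    interval_s=20.0,
    patient_id="P1",
    group="FloTrac",
    times=None,
):
    """Trace from an explicit MAP sample vector on a regular grid."""
    map_values = np.asarray(map_values, dtype=float)
    if times is None:
        times = np.arange(len(map_values)) * interval_s
    return MapTrace(
        patient_id=patient_id,
        group=group,
        times=np.asarray(times, dtype=float),
        map_values=map_values,
        nominal_interval=interval_s,
    )


def step_trace(total_min, blocks, baseline=80.0, interval_s=20.0, **kw):
    """Baseline trace with rectangular MAP blocks.

    ``blocks`` is a list of ``(start_min, end_min, level_mmhg)``; samples
    with start <= t < end take the block level.
    """
    n = int(round(total_min * 60.0 / interval_s)) + 1
    times = np.arange(n) * interval_s
    values = np.full(n, float(baseline))
    for start, end, level in blocks:
        mask = (times >= start * 60.0) & (times < end * 60.0)
        values[mask] = level
    return make_trace(values, interval_s, times=times, **kw)


@pytest.fixture
def square_trace():
    """100 min at MAP 80 with a 10-min block at 55 (the worked example):
    one qualifying event below 65, duration 10 min, area 100 mmHg.min,
    TWA(65) = 1.0 mmHg."""
    return step_trace(100.0, [(30.0, 40.0, 55.0)])


def make_meta(patient_id="P1", group="FloTrac", **kw):
    defaults = dict(
        age_years=60,
        surgery_duration_min=240.0,
        elective=True,
        arrhythmia_flag=False,
        ef_below_35_flag=False,
        severe_stenosis_flag=False,
    )
    defaults.update(kw)
    return PatientMeta(patient_id=patient_id, group=group, **defaults)


def cohort_of(traces):
    return CohortTable(
        traces={t.patient_id: t for t in traces},
        meta={t.patient_id: make_meta(t.patient_id, t.group) for t in traces},
    )
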