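"""MAP-based hypotension-prediction baselines and validation-bias demos.

Commercial hypotension-prediction indices are reported to track MAP so
closely that a monotone transform of MAP behaves as an equivalent
predictor (the "mirror effect"), and their published validation metrics
have been criticised for a label-selection rule that admits only
non-hypotensive segments with MAP above 75 mmHg — a form of label
leakage that inflates apparent performance.  This module makes both
mechanisms computable on any MAP trace:

* ``pseudo_index`` — a logistic mirror of MAP on a 0-100 scale standing
  in for a waveform-derived index (it is *not* a re-implementation of
  any proprietary algorithm);
* ``mirror_correlation`` — lagged Pearson cross-correlation between the
  pseudo-index and MAP;
* ``build_labeled_segments`` — horizon-labelled prediction instances,
  with the biased "negatives require MAP > 75 mmHg" selection rule as
  an explicit option;
* ``evaluate_predictor`` — sensitivity/specificity/AUC for three
  scorers: negated current MAP, the pseudo-index, and LepMAP-style
  linear extrapolation of recent MAP to the prediction horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ValidationError
from .hypotension_burden import EventConfig, detect_events
from .trace_core import MapTrace

SCORERS = ("neg_map", "pseudo_index", "lep_map")
SELECTIONS = ("unbiased", "map_above_75_for_negatives")

#: MAP floor for admitting negative-label segments under the biased
#: selection rule (mmHg): negatives with current MAP at or below this
#: are discarded.
BIASED_NEGATIVE_MAP_FLOOR = 75.0


@dataclass(frozen=True)
class AlarmConfig:
    """Alarm thresholds, horizons and scorer parameters."""

    alarm_map_threshold: float = 72.0
    horizons_min: tuple[float, ...] = (5.0, 10.0, 15.0)
    event_config: EventConfig = field(default_factory=EventConfig)
    extrapolation_window_min: float = 3.0
    index_center_mmhg: float = 75.0
    index_width_mmhg: float = 3.0
    alarm_level: float = 85.0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.horizons_min):
            raise ValidationError("horizons must be positive")
        if not 0 < self.alarm_level < 100:
            raise ValidationError("alarm_level must be in (0, 100)")
        if self.index_width_mmhg <= 0:
            raise ValidationError("index width must be > 0")
        if self.extrapolation_window_min <= 0:
            raise ValidationError("extrapolation window must be > 0")


@dataclass(frozen=True)
class MirrorResult:
    """Lagged cross-correlation of pseudo-index vs MAP."""

    lag0_corr: float
    best_lag: int
    best_corr: float


@dataclass(frozen=True, slots=True)
class LabeledSegment:
    """One prediction instance anchored at a sample time.

    Features (current MAP and the recent-past window) use only
    information available at the anchor; the label uses only the future:
    it is true iff a qualifying hypotensive event starts within the
    horizon after the anchor.
    """

    patient_id: str
    time_s: float
    map_now: float
    past_times: tuple[float, ...]
    past_maps: tuple[float, ...]
    label: bool


@dataclass(frozen=True)
class PredictionMetrics:
    """Alarm performance at one horizon."""

    horizon_min: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    n_pos: int
    n_neg: int


def pseudo_index(map_mmhg, cfg: AlarmConfig = AlarmConfig()):
    """Logistic mirror of MAP on a 0-100 scale.

    ``100 * logistic((center - MAP) / width)``: strictly decreasing in
    MAP, 50 at the center, saturating to 100 (0) as MAP falls (rises).
    """
    m = np.asarray(map_mmhg, dtype=float)
    out = 100.0 * expit((cfg.index_center_mmhg - m) / cfg.index_width_mmhg)
    return float(out) if np.isscalar(map_mmhg) else out


def mirror_correlation(
    trace: MapTrace, cfg: AlarmConfig = AlarmConfig(), max_lag: int = 10
) -> MirrorResult:
    """Pearson cross-correlation between pseudo-index and MAP by lag.

    Lag ``k`` correlates ``index[t]`` with ``map[t + k]``; the result
    reports the lag-0 coefficient and the lag of maximal magnitude
    (ties broken towards lag 0).
    """
    m = trace.map_values
    if np.ptp(m) == 0:
        raise ValidationError(
            f"patient {trace.patient_id}: constant MAP, correlation undefined"
        )
    idx = pseudo_index(m, cfg)
    corrs: dict[int, float] = {}
    n = len(m)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = idx[: n - lag], m[lag:]
        else:
            x, y = idx[-lag:], m[: n + lag]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        corrs[lag] = float(np.corrcoef(x, y)[0, 1])
    if 0 not in corrs:
        raise ValidationError("trace too short for lag-0 correlation")
    best_lag = max(corrs, key=lambda k: (abs(corrs[k]), -abs(k)))
    return MirrorResult(
        lag0_corr=corrs[0], best_lag=best_lag, best_corr=corrs[best_lag]
    )


def build_labeled_segments(
    trace: MapTrace,
    horizon_min: float,
    cfg: AlarmConfig = AlarmConfig(),
    selection: str = "unbiased",
) -> list[LabeledSegment]:
    """Horizon-labelled prediction instances, one per eligible sample.

    A sample anchors a segment if at least ``horizon_min`` of future
    data exists and the sample does not lie inside an ongoing event
    (predicting ongoing hypotension is trivial and would contaminate
    specificity).  The label is true iff a qualifying event starts in
    ``(t, t + horizon]``.  Under ``"map_above_75_for_negatives"``
    selection, negative segments with current MAP <= 75 mmHg are
    discarded — the leaky labelling rule under scrutiny.
    """
    if selection not in SELECTIONS:
        raise ValidationError(f"unknown selection {selection!r}")
    horizon_s = horizon_min * 60.0
    times, maps = trace.times, trace.map_values
    if times[-1] - times[0] < horizon_s:
        return []
    events = detect_events(trace, cfg.event_config)
    starts = np.array([e.start_s for e in events])
    ends = np.array([e.end_s for e in events])
    window_s = cfg.extrapolation_window_min * 60.0
    segments: list[LabeledSegment] = []
    for i, t in enumerate(times):
        if times[-1] - t < horizon_s:
            break
        if len(starts) and np.any((starts <= t) & (t < ends)):
            continue  # inside an ongoing event
        label = bool(len(starts)) and bool(
            np.any((starts > t) & (starts <= t + horizon_s))
        )
        map_now = float(maps[i])
        if (
            selection == "map_above_75_for_negatives"
            and not label
            and map_now <= BIASED_NEGATIVE_MAP_FLOOR
        ):
            continue
        lo = np.searchsorted(times, t - window_s, side="right")
        segments.append(
            LabeledSegment(
                patient_id=trace.patient_id,
                time_s=float(t),
                map_now=map_now,
                past_times=tuple(float(x) for x in times[lo : i + 1]),
                past_maps=tuple(float(x) for x in maps[lo : i + 1]),
                label=label,
            )
        )
    return segments


def _lep_map_score(seg: LabeledSegment, horizon_s: float) -> float:
    """Least-squares line through the recent MAP window, extrapolated to
    the horizon; score = 65 - predicted MAP (positive when hypotension
    is predicted)."""
    t = np.asarray(seg.past_times) - seg.time_s
    m = np.asarray(seg.past_maps)
    if len(t) >= 2 and np.ptp(t) > 0:
        slope, intercept = np.polyfit(t, m, 1)
        predicted = slope * horizon_s + intercept
    else:
        predicted = seg.map_now
    return 65.0 - float(predicted)


def score_segments(
    segments: Sequence[LabeledSegment],
    scorer: str,
    cfg: AlarmConfig = AlarmConfig(),
    horizon_min: float | None = None,
) -> np.ndarray:
    """Risk scores (higher = more alarming) for a segment set."""
    if scorer not in SCORERS:
        raise ValidationError(f"unknown scorer {scorer!r}")
    if scorer == "neg_map":
        return np.array([-s.map_now for s in segments])
    if scorer == "pseudo_index":
        return np.array([pseudo_index(s.map_now, cfg) for s in segments])
    horizon_s = (
        cfg.horizons_min[0] if horizon_min is None else horizon_min
    ) * 60.0
    return np.array([_lep_map_score(s, horizon_s) for s in segments])


def rank_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the rank statistic: the probability that a random positive
    outscores a random negative, ties counting one half.  Raises
    ``ValueError`` on a single-class label set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class segment set")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_predictor(
    segments: Sequence[LabeledSegment],
    scorer: str,
    cfg: AlarmConfig = AlarmConfig(),
    horizon_min: float | None = None,
) -> PredictionMetrics:
    """Sensitivity, specificity and AUC of a scorer on labelled segments.

    The alarm cut-off is scorer-specific: current MAP below
    ``alarm_map_threshold`` for ``neg_map``, index above ``alarm_level``
    for ``pseudo_index``, predicted MAP below 65 for ``lep_map``.  On a
    single-class set the AUC is ``None`` while the defined one of
    sensitivity/specificity is still reported.
    """
    if not segments:
        raise ValidationError("no segments to evaluate")
    labels = np.array([s.label for s in segments], dtype=bool)
    scores = score_segments(segments, scorer, cfg, horizon_min)
    if scorer == "neg_map":
        alarm = scores > -cfg.alarm_map_threshold
    elif scorer == "pseudo_index":
        alarm = scores > cfg.alarm_level
    else:
        alarm = scores > 0.0
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    sensitivity = float(alarm[labels].mean()) if n_pos else None
    specificity = float((~alarm[~labels]).mean()) if n_neg else None
    try:
        auc = rank_auc(scores, labels)
    except ValueError:
        auc = None
    h = cfg.horizons_min[0] if horizon_min is None else horizon_min
    return PredictionMetrics(
        horizon_min=float(h),
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def cohort_segments(
    traces: Sequence[MapTrace],
    horizon_min: float,
    cfg: AlarmConfig = AlarmConfig(),
    selection: str = "unbiased",
) -> list[LabeledSegment]:
    """Pooled labelled segments across a cohort's traces."""
    out: list[LabeledSegment] = []
    for trace in traces:
        out.extend(build_labeled_segments(trace, horizon_min, cfg, selection))
    return out
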