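"""Two-group statistical comparison and report-table construction.

Implements the comparison battery used for perioperative cohort tables:
quantitative variables are screened for normality with the Shapiro-Wilk
test in each group and routed to the unpaired t-test (normal in both
groups; summaries as mean +/- SD) or the two-sided Mann-Whitney U test
(otherwise; summaries as median [Q1; Q3]); proportions use Fisher's
exact test with "n (p%)" summaries.  p-values below alpha (default
0.05) are flagged significant.  No multiple-testing correction is
applied, matching common practice for descriptive cohort tables.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import RoutingError, ValidationError
from .hypotension_burden import PatientBurden
from .trace_core import PatientMeta


@dataclass(frozen=True)
class StatConfig:
    """Knobs of the comparison battery."""

    alpha: float = 0.05
    normality_alpha: float = 0.05
    welch: bool = True            # unpaired t-test variant
    quartile_method: str = "linear"  # numpy quantile method ("type 7")
    percent_rounding: str = "half_up"  # or "truncate"
    percent_decimals: int = 0
    pool_event_durations: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.normality_alpha < 1:
            raise ValidationError("significance levels must be in (0, 1)")
        if self.percent_rounding not in ("half_up", "truncate"):
            raise ValidationError(f"unknown rounding {self.percent_rounding!r}")


@dataclass(frozen=True)
class ComparisonRow:
    """One report-table row: variable, per-group summaries, test, p."""

    variable: str
    summary_a: str
    summary_b: str
    test_used: str  # "t_test" | "mann_whitney" | "fisher_exact"
    p_value: float
    significant: bool


def _fmt(x: float) -> str:
    if not math.isfinite(x):
        return "n/a"
    if x == int(x) and abs(x) < 1e6:
        return str(int(x))
    return f"{x:.2f}"


def mean_sd_summary(values: Sequence[float]) -> str:
    v = np.asarray(values, dtype=float)
    return f"{_fmt(v.mean())} ± {_fmt(v.std(ddof=1) if len(v) > 1 else 0.0)}"


def median_iqr_summary(values: Sequence[float], cfg: StatConfig = StatConfig()) -> str:
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return "n/a"
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=cfg.quartile_method)
    return f"{_fmt(med)} [{_fmt(q1)}; {_fmt(q3)}]"


def format_percent(
    numerator: int,
    denominator: int,
    decimals: int | None = None,
    style: str | None = None,
    cfg: StatConfig = StatConfig(),
) -> str:
    """Render a count as ``"n (p%)"`` at the table's precision.

    ``style`` is ``"half_up"`` (round halves away from zero, the usual
    table convention) or ``"truncate"``.
    """
    if denominator <= 0:
        raise ValidationError("format_percent needs a positive denominator")
    decimals = cfg.percent_decimals if decimals is None else decimals
    style = cfg.percent_rounding if style is None else style
    pct = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    rounding = decimal.ROUND_HALF_UP if style == "half_up" else decimal.ROUND_DOWN
    p = pct.quantize(quantum, rounding=rounding)
    return f"{numerator} ({p}%)"


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution for small tie-free samples (both n <= 8),
    normal approximation with tie correction and continuity correction
    otherwise.
    """
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: no evidence either way
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def route_and_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    cfg: StatConfig = StatConfig(),
    variable: str = "",
) -> ComparisonRow:
    """Normality-routed two-group comparison of a quantitative variable.

    Shapiro-Wilk is run in each group; only if both p-values exceed
    ``cfg.normality_alpha`` is the unpaired t-test used (Welch by
    default), with mean +/- SD summaries.  Otherwise the two-sided
    Mann-Whitney U test is used with median [Q1; Q3] summaries.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise RoutingError(
            "need at least 3 values per group for Shapiro-Wilk routing "
            f"(got {len(a)} and {len(b)})"
        )

    def shapiro_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 0.0  # degenerate: constant data are not normal
        try:
            with np.errstate(all="ignore"):
                p = float(stats.shapiro(v).pvalue)
        except Exception:
            return 0.0
        return p if math.isfinite(p) else 0.0

    normal = (
        shapiro_p(a) > cfg.normality_alpha and shapiro_p(b) > cfg.normality_alpha
    )
    if normal:
        res = stats.ttest_ind(a, b, equal_var=not cfg.welch)
        p = float(res.pvalue)
        test = "t_test"
        summary_a, summary_b = mean_sd_summary(a), mean_sd_summary(b)
    else:
        p = _mann_whitney(a, b)
        test = "mann_whitney"
        summary_a = median_iqr_summary(a, cfg)
        summary_b = median_iqr_summary(b, cfg)
    if not math.isfinite(p):  # identical constant groups under the t-test
        p = 1.0
    return ComparisonRow(
        variable=variable,
        summary_a=summary_a,
        summary_b=summary_b,
        test_used=test,
        p_value=p,
        significant=bool(p < cfg.alpha),
    )


def fisher_2x2(a_yes: int, a_no: int, b_yes: int, b_no: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Central (probability-based) method: the p-value sums hypergeometric
    probabilities of all tables, with the observed margins, no more
    likely than the observed one.
    """
    cells = (a_yes, a_no, b_yes, b_no)
    if any(c < 0 or int(c) != c for c in cells):
        raise ValidationError("fisher_2x2 needs non-negative integer counts")
    if a_yes + a_no == 0 or b_yes + b_no == 0 or a_yes + b_yes == 0 or a_no + b_no == 0:
        raise ValidationError("fisher_2x2: a table margin is zero")
    return float(stats.fisher_exact([[a_yes, a_no], [b_yes, b_no]]).pvalue)


def _quant_row(
    variable: str,
    values_a: Sequence[float],
    values_b: Sequence[float],
    cfg: StatConfig,
) -> ComparisonRow:
    """Quantitative row with graceful handling of tiny/empty groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) >= 3 and len(b) >= 3:
        return route_and_test(a, b, cfg, variable=variable)
    # degenerate sample sizes: fall back to Mann-Whitney or an
    # uninformative row, keeping the median-style summaries
    if len(a) and len(b):
        p = _mann_whitney(a, b)
    elif len(a) == 0 and len(b) == 0:
        p = 1.0
    else:
        p = math.nan
    return ComparisonRow(
        variable=variable,
        summary_a=median_iqr_summary(a, cfg) if len(a) else "0 [0; 0]",
        summary_b=median_iqr_summary(b, cfg) if len(b) else "0 [0; 0]",
        test_used="mann_whitney",
        p_value=p,
        significant=bool(p < cfg.alpha) if math.isfinite(p) else False,
    )


def _count_row(
    variable: str, a_yes: int, n_a: int, b_yes: int, n_b: int, cfg: StatConfig
) -> ComparisonRow:
    if (a_yes + b_yes == 0) or (a_yes == n_a and b_yes == n_b):
        p = 1.0  # homogeneous column: Fisher margin degenerate
    else:
        p = fisher_2x2(a_yes, n_a - a_yes, b_yes, n_b - b_yes)
    return ComparisonRow(
        variable=variable,
        summary_a=format_percent(a_yes, n_a, cfg=cfg),
        summary_b=format_percent(b_yes, n_b, cfg=cfg),
        test_used="fisher_exact",
        p_value=p,
        significant=bool(p < cfg.alpha),
    )


def build_report(
    burdens: Sequence[PatientBurden],
    meta: Mapping[str, PatientMeta] | Sequence[PatientMeta],
    cfg: StatConfig = StatConfig(),
    thresholds: Sequence[float] = (65.0, 50.0),
) -> list[ComparisonRow]:
    """Emit the full report-table row set for a two-group cohort.

    Descriptive rows (age, surgery duration, monitoring time) are
    followed, per threshold, by: TWA, number of patients with events,
    events per patient, per-event duration (pooled across a group's
    patients by default; per-patient means if
    ``cfg.pool_event_durations`` is false), cumulative time below
    threshold, and time below threshold as % of monitoring time.
    """
    if isinstance(meta, Mapping):
        meta_map = dict(meta)
    else:
        meta_map = {m.patient_id: m for m in meta}
    groups: list[str] = []
    for b in burdens:
        if b.group not in groups:
            groups.append(b.group)
    if len(groups) != 2:
        raise ValidationError(
            f"build_report requires exactly two groups, found {groups!r}"
        )
    ga, gb = groups
    in_a = [b for b in burdens if b.group == ga]
    in_b = [b for b in burdens if b.group == gb]
    if not in_a or not in_b:
        raise ValidationError("build_report: one group is empty")

    rows: list[ComparisonRow] = []
    rows.append(
        _quant_row(
            "Age in years",
            [meta_map[b.patient_id].age_years for b in in_a],
            [meta_map[b.patient_id].age_years for b in in_b],
            cfg,
        )
    )
    rows.append(
        _quant_row(
            "Duration of surgery in minutes",
            [meta_map[b.patient_id].surgery_duration_min for b in in_a],
            [meta_map[b.patient_id].surgery_duration_min for b in in_b],
            cfg,
        )
    )
    rows.append(
        _quant_row(
            "Time of hemodynamic monitoring in minutes",
            [b.monitoring_min for b in in_a],
            [b.monitoring_min for b in in_b],
            cfg,
        )
    )
    for thr in thresholds:
        t = f"{thr:g}"
        rows.append(
            _quant_row(
                f"Time-weighted average for MAP < {t} mmHg, mmHg",
                [b.at(thr).twa_mmhg for b in in_a],
                [b.at(thr).twa_mmhg for b in in_b],
                cfg,
            )
        )
        rows.append(
            _count_row(
                f"Number of patients with hypotensive events < {t} mmHg, n (%)",
                sum(b.at(thr).any_event for b in in_a),
                len(in_a),
                sum(b.at(thr).any_event for b in in_b),
                len(in_b),
                cfg,
            )
        )
        rows.append(
            _quant_row(
                f"Number of hypotensive events < {t} mmHg per patient",
                [b.at(thr).n_events for b in in_a],
                [b.at(thr).n_events for b in in_b],
                cfg,
            )
        )
        if cfg.pool_event_durations:
            dur_a = [d for b in in_a for d in b.at(thr).event_durations_min]
            dur_b = [d for b in in_b for d in b.at(thr).event_durations_min]
        else:
            dur_a = [b.at(thr).mean_event_duration_min for b in in_a if b.at(thr).any_event]
            dur_b = [b.at(thr).mean_event_duration_min for b in in_b if b.at(thr).any_event]
        rows.append(
            _quant_row(
                f"Duration of hypotensive events < {t} mmHg in minutes",
                dur_a,
                dur_b,
                cfg,
            )
        )
        rows.append(
            _quant_row(
                f"Total time in hypotension < {t} mmHg in minutes",
                [b.at(thr).total_time_below_min for b in in_a],
                [b.at(thr).total_time_below_min for b in in_b],
                cfg,
            )
        )
        rows.append(
            _quant_row(
                f"Total time in hypotension < {t} mmHg as percentage of the monitoring time",
                [b.at(thr).pct_time_below for b in in_a],
                [b.at(thr).pct_time_below for b in in_b],
                cfg,
            )
        )
    return rows


def report_frame(rows: Sequence[ComparisonRow], group_a: str, group_b: str):
    """Report rows as a DataFrame (variable, group A, group B, p)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            group_a: [r.summary_a for r in rows],
            group_b: [r.summary_b for r in rows],
            "test": [r.test_used for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def report_markdown(rows: Sequence[ComparisonRow], group_a: str, group_b: str) -> str:
    """Aligned markdown rendering of a comparison table."""
    header = ["Variable", group_a, group_b, "p"]
    body = [
        [r.variable, r.summary_a, r.summary_b, f"{r.p_value:.6g}" if math.isfinite(r.p_value) else "n/a"]
        for r in rows
    ]
    widths = [max(len(row[i]) for row in [header] + body) for i in range(4)]
    lines = [
        "| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |",
        "| " + " | ".join("-" * w for w in widths) + " |",
    ]
    for row in body:
        lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |")
    return "\n".join(lines) + "\n"
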