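"""Synthetic two-group MAP cohort generator.

No public dataset of intraoperative MAP trend exports exists for this
setting, so every downstream stage is exercised on simulated cohorts
that emulate the structure of the study population: two monitoring arms
of ~61/62 patients, monitoring time roughly 241 +/- 130 min, and a
group contrast in hypotension burden (the comparator arm has more,
longer and deeper hypotensive episodes than the prediction-guided arm).

The generative model per patient is deliberately minimal:

* monitoring duration ~ Normal(mean, sd) truncated at a floor that
  respects the >120 min inclusion rule;
* a patient-level baseline MAP ~ Normal(85, 8) mmHg;
* within-patient fluctuation as a stationary AR(1) process around the
  baseline (mean-reversion coefficient ``ar1_phi`` per 20 s sample,
  innovation SD ``noise_sd``);
* hypotensive episodes arriving as a Poisson process, each subtracting
  a raised-cosine dip whose peak takes the noise-free MAP down to
  ``65 - depth`` mmHg over a truncated-normal duration, placed
  uniformly in time without overlap.

Episode depths are resampled into (0, 15) mmHg for ordinary episodes so
their nadir stays above 50 mmHg; with probability ``severe_fraction``
an episode is severe and draws its depth above 15 mmHg, putting the
nadir below 50 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError, ValidationError
from .trace_core import CohortTable, MapTrace, PatientMeta

#: Severity boundary: an episode whose depth below 65 exceeds this takes
#: the nadir below the 50 mmHg severe-hypotension threshold.
SEVERE_DEPTH_MMHG = 15.0

_MAX_PLACEMENT_ATTEMPTS = 1000
_MAX_EPISODE_LOAD = 0.8  # fraction of monitoring time episodes may occupy


@dataclass(frozen=True)
class GroupEpisodeModel:
    """Episode-process parameters for one monitoring arm."""

    episode_rate_per_hour: float
    depth_mean_mmhg: float
    depth_sd_mmhg: float
    duration_mean_min: float
    duration_sd_min: float
    severe_fraction: float

    def validate(self, label: str) -> None:
        if self.episode_rate_per_hour < 0:
            raise ConfigError(f"{label}: episode rate must be >= 0")
        if self.depth_sd_mmhg < 0 or self.duration_sd_min < 0:
            raise ConfigError(f"{label}: SDs must be >= 0")
        if self.duration_mean_min <= 0:
            raise ConfigError(f"{label}: episode duration mean must be > 0")
        if not 0.0 <= self.severe_fraction <= 1.0:
            raise ConfigError(f"{label}: severe_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterisation of the two-group trace generator."""

    n_group_a: int = 61
    n_group_b: int = 62
    group_a_label: str = "FloTrac"
    group_b_label: str = "HPI"
    duration_mean_min: float = 241.0
    duration_sd_min: float = 130.0
    duration_floor_min: float = 121.0
    baseline_map_mean: float = 85.0
    baseline_map_sd_between_patients: float = 8.0
    ar1_phi: float = 0.9
    noise_sd: float = 2.5
    sample_interval_s: float = 20.0
    group_a: GroupEpisodeModel = field(
        default_factory=lambda: GroupEpisodeModel(
            episode_rate_per_hour=1.2,
            depth_mean_mmhg=8.0,
            depth_sd_mmhg=3.0,
            duration_mean_min=6.0,
            duration_sd_min=2.0,
            severe_fraction=0.15,
        )
    )
    group_b: GroupEpisodeModel = field(
        default_factory=lambda: GroupEpisodeModel(
            episode_rate_per_hour=0.45,
            depth_mean_mmhg=4.0,
            depth_sd_mmhg=2.0,
            duration_mean_min=2.5,
            duration_sd_min=1.0,
            severe_fraction=0.02,
        )
    )
    forced_episode_count: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ConfigError("group sizes must be >= 0")
        if self.duration_sd_min < 0 or self.noise_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if self.baseline_map_sd_between_patients < 0:
            raise ConfigError("between-patient baseline SD must be >= 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ConfigError("ar1_phi must be in [0, 1)")
        if self.duration_floor_min <= 0:
            raise ConfigError("duration_floor_min must be > 0")
        if self.sample_interval_s <= 0:
            raise ConfigError("sample_interval_s must be > 0")
        self.group_a.validate("group A")
        self.group_b.validate("group B")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
    max_attempts: int = 10000,
) -> float:
    """Rejection-sampled truncated normal (keeps the shape unskewed for
    mild truncation)."""
    if sd == 0:
        if low <= mean <= high:
            return mean
        raise ConfigError("degenerate truncated normal outside its bounds")
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise ConfigError(
        f"could not sample N({mean}, {sd}) truncated to ({low}, {high})"
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise of length n."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_trace(
    patient_id: str,
    group: str,
    duration_min: float,
    episodes: list[tuple[float, float, float]],
    config: SyntheticCohortConfig,
    baseline_map: float | None = None,
    rng: np.random.Generator | None = None,
) -> MapTrace:
    """Deterministic trace builder: baseline + AR(1) noise + episode dips.

    ``episodes`` is a list of ``(start_min, depth_mmhg, duration_min)``
    tuples; episodes must lie within the trace and not overlap.  Each
    episode subtracts a raised-cosine dip scaled so that, noise-free,
    the trace minimum inside the episode equals ``65 - depth`` mmHg.
    With ``config.noise_sd == 0`` the output is fully determined by the
    arguments; otherwise ``rng`` supplies the noise stream.
    """
    baseline = config.baseline_map_mean if baseline_map is None else baseline_map
    episodes = sorted(episodes, key=lambda e: e[0])
    prev_end = -np.inf
    for start, depth, dur in episodes:
        if start < 0 or start + dur > duration_min:
            raise ValidationError(
                f"episode ({start:g}, {depth:g}, {dur:g}) outside [0, {duration_min:g}] min"
            )
        if dur <= 0 or depth <= 0:
            raise ValidationError("episode depth and duration must be > 0")
        if start < prev_end:
            raise ValidationError("episodes overlap")
        prev_end = start + dur
    n = int(np.floor(duration_min * 60.0 / config.sample_interval_s)) + 1
    times = np.arange(n) * config.sample_interval_s
    values = np.full(n, float(baseline))
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        values += _ar1(rng, n, config.ar1_phi, config.noise_sd)
    t_min = times / 60.0
    for start, depth, dur in episodes:
        amplitude = baseline - (65.0 - depth)
        if amplitude <= 0:
            continue  # baseline already at/below the target nadir
        u = (t_min - start) / dur
        support = (u >= 0) & (u <= 1)
        values[support] -= amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[support]))
    return MapTrace(
        patient_id=patient_id,
        group=group,
        times=times,
        map_values=values,
        nominal_interval=config.sample_interval_s,
    )


def _draw_episodes(
    rng: np.random.Generator,
    model: GroupEpisodeModel,
    duration_min: float,
    config: SyntheticCohortConfig,
) -> list[tuple[float, float, float]]:
    if config.forced_episode_count is not None:
        n_ep = config.forced_episode_count
    else:
        n_ep = int(rng.poisson(model.episode_rate_per_hour * duration_min / 60.0))
    if n_ep == 0:
        return []
    durations = [
        _truncated_normal(rng, model.duration_mean_min, model.duration_sd_min, low=0.0)
        for _ in range(n_ep)
    ]
    if sum(durations) > _MAX_EPISODE_LOAD * duration_min:
        raise ConfigError(
            f"episodes would occupy {sum(durations):.1f} of {duration_min:.1f} min "
            f"(> {_MAX_EPISODE_LOAD:.0%}); infeasible placement"
        )
    depths = []
    for _ in range(n_ep):
        if rng.uniform() < model.severe_fraction:
            depths.append(
                _truncated_normal(
                    rng,
                    model.depth_mean_mmhg + SEVERE_DEPTH_MMHG,
                    model.depth_sd_mmhg,
                    low=SEVERE_DEPTH_MMHG,
                )
            )
        else:
            depths.append(
                _truncated_normal(
                    rng, model.depth_mean_mmhg, model.depth_sd_mmhg,
                    low=0.0, high=SEVERE_DEPTH_MMHG,
                )
            )
    placed: list[tuple[float, float, float]] = []
    for depth, dur in zip(depths, durations):
        ok = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            start = rng.uniform(0.0, duration_min - dur)
            if all(start + dur <= s or start >= s + d for s, _, d in placed):
                placed.append((start, depth, dur))
                ok = True
                break
        if not ok:
            raise ConfigError(
                "could not place episodes without overlap after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return sorted(placed, key=lambda e: e[0])


def simulate_cohort(config: SyntheticCohortConfig = SyntheticCohortConfig()) -> CohortTable:
    """Simulate a full two-group cohort.

    A single seeded RNG stream drives the whole cohort in a fixed
    patient order, so identical config + seed reproduces the cohort
    bit-for-bit.  Generated metadata always satisfies the inclusion
    screen (elective adult surgery longer than the duration floor, no
    exclusion flags).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    traces: dict[str, MapTrace] = {}
    meta: dict[str, PatientMeta] = {}
    arms = (
        (config.group_a_label, config.n_group_a, config.group_a),
        (config.group_b_label, config.n_group_b, config.group_b),
    )
    for label, n_patients, model in arms:
        for i in range(n_patients):
            pid = f"{label}-{i + 1:03d}"
            duration = _truncated_normal(
                rng,
                config.duration_mean_min,
                config.duration_sd_min,
                low=config.duration_floor_min,
            )
            baseline = rng.normal(
                config.baseline_map_mean, config.baseline_map_sd_between_patients
            )
            episodes = _draw_episodes(rng, model, duration, config)
            traces[pid] = simulate_trace(
                pid, label, duration, episodes, config,
                baseline_map=baseline, rng=rng,
            )
            meta[pid] = PatientMeta(
                patient_id=pid,
                group=label,
                age_years=int(rng.integers(19, 86)),
                surgery_duration_min=float(duration),
                elective=True,
                arrhythmia_flag=False,
                ef_below_35_flag=False,
                severe_stenosis_flag=False,
            )
    return CohortTable(traces=traces, meta=meta)


def symmetric_config(
    base: SyntheticCohortConfig | None = None,
    n_per_group: int | None = None,
    seed: int = 0,
) -> SyntheticCohortConfig:
    """A null-contrast config: both arms share group A's episode model.

    Used for type-I-error calibration, where the two groups must be
    generated from identical distributions.
    """
    cfg = base if base is not None else SyntheticCohortConfig()
    kwargs: dict = {"group_b": cfg.group_a, "seed": seed}
    if n_per_group is not None:
        kwargs["n_group_a"] = n_per_group
        kwargs["n_group_b"] = n_per_group
    return replace(cfg, **kwargs)
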