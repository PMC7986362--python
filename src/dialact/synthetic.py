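"""Synthetic dialysis-cohort generator.

Emulates the statistical structure the downstream analysis assumes, so
every stage is testable without any participant data: thrice-weekly
~4-h dialysis sessions (morning or afternoon slot) spent sedentary,
early waking before morning sessions, five-state daily behaviour
schedules whose cohort-average durations match the study day-type
profiles, an age-activity gradient and a leg-weakness activity deficit,
random non-wear gaps, and (at raw tier) device miscalibration.

Two fidelity tiers: ``epoch`` emits 30-s epochs with vector magnitude,
class-conditional Gaussian feature vectors and true labels, and drives
cohort-scale recovery tests; ``raw`` emits a triaxial acceleration
process (slowly precessing gravity orientation + radial oscillation +
noise) for validating preprocessing on spans of hours to days.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .questionnaires import KCCQ_DOMAINS, EQ5DResponse, KCCQResponse
from .raw_io import EpochSeries, ParticipantRecord, RawTrace

__all__ = [
    "GeneratorConfig",
    "BehaviourSchedule",
    "oxford_cohort_config",
    "generate_cohort",
    "generate_schedule",
    "synthesize_signal",
    "generate_participant_epochs",
    "generate_questionnaires",
    "generate_control_pool",
    "CONTROL_SCENARIOS",
]

STATES = ("walking", "light_tasks", "moderate", "sedentary", "sleep")

# typical uninterrupted-bout lengths (minutes) used to chop daily state
# totals into semi-Markov segments, so the HMM has realistic run-lengths
SEGMENT_MEAN_MIN = {"walking": 6.0, "light_tasks": 12.0, "moderate": 10.0, "sedentary": 35.0}

SLOT_WINDOWS = {"morning": (7.5, 11.5), "afternoon": (13.0, 17.0)}

SEASONS = ("winter", "spring", "summer", "autumn")

WEEKDAY_PATTERNS = ((0, 2, 4), (1, 3, 5))  # Mon/Wed/Fri or Tue/Thu/Sat


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic cohort; defaults are the dialysis-cohort
    study conditions (n = 73, 12 full wear days, day-type behaviour profiles
    and activity levels from the published cohort tables)."""

    n_participants: int = 73
    wear_days: int = 12

    # hours/day per behaviour state, by day type; each must sum to 24
    behaviour_day_profile: dict = field(
        default_factory=lambda: {
            "dialysis": {
                "walking": 0.90,
                "light_tasks": 0.57,
                "moderate": 0.45,
                "sedentary": 13.58,
                "sleep": 8.50,
            },
            "non-dialysis": {
                "walking": 1.08,
                "light_tasks": 0.78,
                "moderate": 0.64,
                "sedentary": 12.90,
                "sleep": 8.60,
            },
        }
    )
    # cohort-level mean daily ENMO by day type, mg
    daytype_vm_mg: dict = field(
        default_factory=lambda: {"dialysis": 14.8, "non-dialysis": 16.2}
    )

    dialysis_session_hours: float = 4.0
    slot_split: float = 0.5  # proportion with a morning slot

    # realized (post-truncation) moments of the age distribution
    age_mean: float = 66.5
    age_sd: float = 14.0
    age_min: float = 26.0
    age_max: float = 87.0
    female_fraction: float = 22 / 73
    leg_weakness_fraction: float = 43 / 73

    # age-activity gradient: group-level deviations (mg) per age third.
    # The published tertile means are not collinear in age, so the gradient
    # is a step profile over the tertile bins; set to None to fall back to
    # the linear age_activity_slope.
    age_activity_deltas: dict | None = field(
        default_factory=lambda: {"young": 4.0, "middle": -1.3, "old": -2.7}
    )
    age_tertile_bounds: tuple = (62.0, 74.0)
    age_activity_slope: float = -0.25  # mg per year; used when deltas is None
    leg_weakness_activity_deficit: float = 5.2  # mg, leg-weak vs not
    participant_vm_sd: float = 4.2  # residual between-participant sd at the cohort level, mg
    day_vm_sd: float = 1.0  # within-participant day-to-day sd, mg
    sleep_hours_sd: float = 0.3  # day-to-day sd of nightly sleep, h

    # base epoch-level ENMO (mean, sd) per state, mg; rescaled per day so the
    # schedule-implied expected daily mean equals the participant's truth
    state_vm_distributions: dict = field(
        default_factory=lambda: {
            "walking": (110.0, 35.0),
            "light_tasks": (40.0, 20.0),
            "moderate": (140.0, 45.0),
            "sedentary": (9.0, 8.0),
            "sleep": (4.0, 4.0),
        }
    )

    nonwear_gaps_per_day: float = 0.15
    nonwear_gap_min_minutes: float = 60.0
    nonwear_gap_max_minutes: float = 180.0

    calibration_offset_sd_g: float = 0.02
    calibration_gain_sd: float = 0.01

    # class-conditional Gaussian features (unit sd); separation controls
    # classifier difficulty (~2.5 = a high-accuracy regime, ~1.0 = the
    # noisy ~74%-accuracy regime)
    feature_separation: float = 2.5
    n_features: int = 6

    questionnaire_strength: float = 0.8  # rank-correlation strength in [0, 1]

    tier: str = "epoch"  # "epoch" | "raw"
    raw_rate_hz: float = 25.0
    raw_noise_mg: float = 8.0
    max_raw_span_h: float = 72.0

    camera_subset_size: int = 25
    camera_days: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        for ty, prof in self.behaviour_day_profile.items():
            tot = sum(prof.values())
            if abs(tot - 24.0) > 1e-6:
                raise ValueError(f"{ty} profile hours sum to {tot}, not 24")
            if any(h < 0 for h in prof.values()):
                raise ValueError(f"{ty} profile has negative hours")
        for name in ("slot_split", "female_fraction", "leg_weakness_fraction",
                     "questionnaire_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("participant_vm_sd", "day_vm_sd", "sleep_hours_sd",
                     "calibration_gain_sd", "calibration_offset_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tier not in ("epoch", "raw"):
            raise ValueError(f"tier must be 'epoch' or 'raw', got {self.tier!r}")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        # yaml gives lists for the (mean, sd) pairs
        if "state_vm_distributions" in raw:
            raw["state_vm_distributions"] = {
                k: tuple(v) for k, v in raw["state_vm_distributions"].items()
            }
        return cls(**raw)

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def oxford_cohort_config(**overrides) -> GeneratorConfig:
    """The packaged default cohort configuration (n = 73, 12 wear days)."""
    return GeneratorConfig(**overrides)


@dataclass
class BehaviourSchedule:
    """One day tiled exactly by behaviour segments (hours since midnight)."""

    day: dt.date
    day_type: str  # "dialysis" | "non-dialysis"
    segments: list  # [(start_h, end_h, state), ...] ordered, tiling [0, 24]

    def __post_init__(self) -> None:
        pos = 0.0
        for start, end, state in self.segments:
            if abs(start - pos) > 1e-9 or end < start - 1e-12:
                raise ValueError("segments must tile the day without gaps or overlap")
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            pos = end
        if abs(pos - 24.0) > 1e-9:
            raise ValueError(f"segments cover {pos} h, not 24")

    def hours_per_state(self) -> dict:
        out = {s: 0.0 for s in STATES}
        for start, end, state in self.segments:
            out[state] += end - start
        return out

    def state_per_epoch(self, epoch_s: float = 30.0) -> np.ndarray:
        """State of each epoch of the day, assigned by epoch midpoint."""
        n = int(round(24 * 3600 / epoch_s))
        mid = (np.arange(n) + 0.5) * epoch_s / 3600.0
        bounds = np.asarray([seg[1] for seg in self.segments])
        seg_idx = np.searchsorted(bounds, mid, side="right").clip(max=len(self.segments) - 1)
        states = np.asarray([seg[2] for seg in self.segments], dtype=object)
        return states[seg_idx]


# ---------------------------------------------------------------------------
# Cohort generation


_NOMINAL_CACHE: dict[tuple, tuple[float, float]] = {}


def _nominal_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Nominal (mu, sigma) whose [lo, hi]-truncation has the given moments.

    Published cohort age statistics are realized (post-truncation) moments;
    drawing from N(mean, sd) directly would understate both.
    """
    key = (round(mean, 6), round(sd, 6), round(lo, 6), round(hi, 6))
    if key not in _NOMINAL_CACHE:
        from scipy import optimize
        from scipy import stats as sps

        def moments(p):
            mu, sig = p
            a, b = (lo - mu) / sig, (hi - mu) / sig
            m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
            return [m - mean, np.sqrt(v) - sd]

        sol, _, ok, _ = optimize.fsolve(moments, [mean, sd], full_output=True)
        _NOMINAL_CACHE[key] = tuple(sol) if ok == 1 else (mean, sd)
    return _NOMINAL_CACHE[key]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sample so the realized moments match (mean, sd)."""
    mu, sig = _nominal_truncnorm(mean, sd, lo, hi)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mu, sig, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _exact_count_mask(rng, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(n * fraction) True entries."""
    k = int(round(n * fraction))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Draw the cohort and its per-participant activity truth.

    Deterministic given ``config.seed``. Each participant's true day-type
    mean ENMO is the cohort day-type level shifted by the age gradient
    (``age_activity_slope`` x (age - cohort mean age)), the leg-weakness
    deficit (applied around the cohort leg-weakness fraction so the
    cohort mean is preserved) and a residual participant effect. True
    behaviour hours scale the active states by the participant's relative
    activity, absorbing the balance into sedentary time.

    Returns ``(records, truth)`` where ``truth`` has one row per
    participant with the true vm and state-hours by day type.
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_participants
    ages = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n
    )
    female = _exact_count_mask(rng, n, config.female_fraction)
    leg_weak = _exact_count_mask(rng, n, config.leg_weakness_fraction)
    breathless = rng.random(n) < 0.49
    listed = rng.random(n) < 0.14
    arrhythmia = rng.random(n) < 0.47
    cvd_dm = rng.random(n) < 0.58
    morning = _exact_count_mask(rng, n, config.slot_split)
    patterns = [WEEKDAY_PATTERNS[i] for i in rng.integers(0, len(WEEKDAY_PATTERNS), size=n)]
    seasons = [SEASONS[i] for i in rng.integers(0, 4, size=n)]

    # reference level: weekly mix of day-type means under thrice-weekly sessions
    cohort_overall = (
        3.0 * config.daytype_vm_mg["dialysis"] + 4.0 * config.daytype_vm_mg["non-dialysis"]
    ) / 7.0
    if config.age_activity_deltas is not None:
        lo_b, hi_b = config.age_tertile_bounds
        keys = np.where(ages <= lo_b, "young", np.where(ages <= hi_b, "middle", "old"))
        age_delta = np.asarray([config.age_activity_deltas[k] for k in keys])
    else:
        age_delta = config.age_activity_slope * ages
    # gradients are centred on the realized cohort (sample mean, exact
    # leg-weakness count), shifting subgroups without moving the cohort mean
    structural = (
        cohort_overall
        + (age_delta - age_delta.mean())
        - config.leg_weakness_activity_deficit
        * (leg_weak.astype(float) - config.leg_weakness_fraction)
    ) / cohort_overall
    # residual participant effect is multiplicative (mean-one lognormal):
    # activity spread scales with activity level, matching the published
    # pattern of larger young-group and smaller old-group dispersions
    s = config.participant_vm_sd / cohort_overall
    noise = np.exp(rng.normal(-0.5 * np.log1p(s * s), np.sqrt(np.log1p(s * s)), size=n))
    factor = structural * noise
    vm_d = np.maximum(config.daytype_vm_mg["dialysis"] * factor, 2.0)
    vm_n = np.maximum(config.daytype_vm_mg["non-dialysis"] * factor, 2.0)
    vm_overall = (3.0 * vm_d + 4.0 * vm_n) / 7.0
    rel = vm_overall / cohort_overall

    records: list[ParticipantRecord] = []
    rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        records.append(
            ParticipantRecord(
                id=pid,
                age=float(ages[i]),
                sex="female" if female[i] else "male",
                dialysis_weekdays=patterns[i],
                slot="morning" if morning[i] else "afternoon",
                leg_weakness=bool(leg_weak[i]),
                breathlessness=bool(breathless[i]),
                listed_transplant=bool(listed[i]),
                arrhythmia=bool(arrhythmia[i]),
                cvd_or_dm=bool(cvd_dm[i]),
                wear_season=seasons[i],
            )
        )
        row = {
            "id": pid,
            "age": float(ages[i]),
            "sex": "female" if female[i] else "male",
            "leg_weakness": bool(leg_weak[i]),
            "slot": "morning" if morning[i] else "afternoon",
            "vm_dialysis": float(vm_d[i]),
            "vm_non-dialysis": float(vm_n[i]),
            "vm_overall": float(vm_overall[i]),
        }
        for ty in ("dialysis", "non-dialysis"):
            hours = _participant_hours(config.behaviour_day_profile[ty], float(rel[i]))
            for s in STATES:
                row[f"hours_{s}_{ty}"] = hours[s]
        rows.append(row)
    return records, pd.DataFrame(rows)


def _participant_hours(profile: dict, rel: float) -> dict:
    """Scale active-state hours by relative activity; sedentary absorbs the rest."""
    hours = {s: profile[s] for s in STATES}
    for s in ("walking", "light_tasks", "moderate"):
        hours[s] = profile[s] * rel
    hours["sedentary"] = 24.0 - hours["walking"] - hours["light_tasks"] - hours["moderate"] - hours["sleep"]
    if hours["sedentary"] < 0:
        # extremely active tail: rescale actives to keep the day feasible
        scale = (24.0 - hours["sleep"]) / (
            hours["walking"] + hours["light_tasks"] + hours["moderate"]
        )
        for s in ("walking", "light_tasks", "moderate"):
            hours[s] *= scale * 0.95
        hours["sedentary"] = 24.0 - sum(hours[s] for s in ("walking", "light_tasks", "moderate", "sleep"))
    return hours


# ---------------------------------------------------------------------------
# Daily schedules


def _chop(total_h: float, mean_min: float, rng) -> list[float]:
    """Cut a state's daily total into bout-length chunks (hours)."""
    chunks = []
    remaining = total_h
    mean_h = mean_min / 60.0
    while remaining > 1e-9:
        d = min(remaining, rng.gamma(2.0, mean_h / 2.0) + 1.0 / 60.0)
        chunks.append(d)
        remaining -= d
    return chunks


def generate_schedule(
    participant: ParticipantRecord,
    day: dt.date,
    config: GeneratorConfig,
    seed: int | None = None,
    truth_hours: dict | None = None,
    rng: np.random.Generator | None = None,
) -> BehaviourSchedule:
    """Simulate one day's behaviour segments for a participant.

    Sleep is split across midnight (a morning part ending at wake time and
    an evening part from sleep onset); participants with a morning
    dialysis slot wake early (~04:30-05:30) on dialysis days, producing
    the characteristic 4-6 a.m. activity. On dialysis days a contiguous
    sedentary session block of ``dialysis_session_hours`` is placed in
    the assigned slot window. The waking remainder is tiled with
    shuffled state bouts whose daily totals jitter around the
    participant's true hours, so long-run averages converge to truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    is_dialysis = bool(
        participant.dialysis_weekdays and day.weekday() in participant.dialysis_weekdays
    )
    day_type = "dialysis" if is_dialysis else "non-dialysis"
    truth = truth_hours or config.behaviour_day_profile[day_type]

    sleep_h = float(np.clip(rng.normal(truth["sleep"], config.sleep_hours_sd), 5.0, 12.0))
    if is_dialysis and participant.slot == "morning":
        wake = float(np.clip(rng.normal(4.75, 0.5), 3.5, 6.0))
    else:
        wake = float(np.clip(rng.normal(7.0, 0.7), 5.0, 9.0))
    wake = float(np.clip(wake, 0.5, sleep_h - 0.5))
    onset = 24.0 - (sleep_h - wake)

    awake = onset - wake
    # mean-one lognormal day-to-day jitter on active-state hours
    jitter = np.exp(rng.normal(-0.5 * 0.15**2, 0.15, size=3))
    w_h = truth["walking"] * jitter[0]
    l_h = truth["light_tasks"] * jitter[1]
    m_h = truth["moderate"] * jitter[2]
    session = config.dialysis_session_hours if is_dialysis else 0.0
    max_active = awake - session - 0.5
    if w_h + l_h + m_h > max_active:
        scale = max_active / (w_h + l_h + m_h)
        w_h, l_h, m_h = w_h * scale, l_h * scale, m_h * scale
    sed_h = awake - w_h - l_h - m_h - session  # sedentary outside the session

    block = None
    if is_dialysis:
        lo, hi = SLOT_WINDOWS[participant.slot or "morning"]
        start = float(np.clip(lo + rng.uniform(-0.25, 0.5), wake, onset - session))
        block = (start, start + session)

    chunks = []
    for state, hours in (
        ("walking", w_h),
        ("light_tasks", l_h),
        ("moderate", m_h),
        ("sedentary", sed_h),
    ):
        chunks += [(state, d) for d in _chop(hours, SEGMENT_MEAN_MIN[state], rng)]
    rng.shuffle(chunks)

    intervals = [(wake, block[0]), (block[1], onset)] if block else [(wake, onset)]
    segments = [(0.0, wake, "sleep")]
    ci = 0
    carry = 0.0  # remainder of a chunk split across the session block
    carry_state = None
    for iv_start, iv_end in intervals:
        pos = iv_start
        if block and abs(iv_start - block[1]) < 1e-12:
            segments.append((block[0], block[1], "sedentary"))
        while pos < iv_end - 1e-9:
            if carry > 1e-9:
                state, d = carry_state, carry
                carry = 0.0
            elif ci < len(chunks):
                state, d = chunks[ci]
                ci += 1
            else:
                state, d = "sedentary", iv_end - pos
            take = min(d, iv_end - pos)
            if d - take > 1e-9:
                carry, carry_state = d - take, state
            end = pos + take
            if iv_end - end < 1e-6:  # snap: float accumulation must not leave slivers
                end = iv_end
            segments.append((pos, end, state))
            pos = end
    segments.append((onset, 24.0, "sleep"))
    # drop zero-length pieces and merge adjacent same-state segments
    merged: list[tuple[float, float, str]] = []
    for start, end, state in segments:
        if end - start < 1e-12:
            continue
        if merged and merged[-1][2] == state:
            merged[-1] = (merged[-1][0], end, state)
        else:
            merged.append((start, end, state))
    return BehaviourSchedule(day=day, day_type=day_type, segments=merged)


# ---------------------------------------------------------------------------
# Signal synthesis


def _truncnorm_mean(mean: float, sd: float) -> float:
    """E[max(0, N(mean, sd))] — the zero-truncated normal mean."""
    if sd == 0:
        return max(mean, 0.0)
    z = mean / sd
    return mean * _phi_cdf(z) + sd * _phi_pdf(z)


def _phi_pdf(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)


def _phi_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _feature_means(config: GeneratorConfig) -> np.ndarray:
    """Class-conditional Gaussian centres: separated unit directions."""
    m = np.zeros((len(STATES), config.n_features))
    for i in range(len(STATES)):
        m[i, i % config.n_features] = config.feature_separation
    return m


def _epoch_day(
    schedule: BehaviourSchedule,
    config: GeneratorConfig,
    rng: np.random.Generator,
    day_vm_target: float,
    with_features: bool = True,
    epoch_s: float = 30.0,
) -> EpochSeries:
    """One day of 30-s epochs: vm, features, true labels, non-wear gaps."""
    states = schedule.state_per_epoch(epoch_s)
    n = len(states)
    state_idx = np.asarray([STATES.index(s) for s in states])

    base = config.state_vm_distributions
    trunc_means = np.asarray([_truncnorm_mean(*base[s]) for s in STATES])
    frac = np.bincount(state_idx, minlength=len(STATES)) / n
    expected = float(frac @ trunc_means)
    scale = max(day_vm_target, 0.5) / expected

    mu = np.asarray([base[s][0] for s in STATES])[state_idx] * scale
    sd = np.asarray([base[s][1] for s in STATES])[state_idx] * scale
    vm = np.maximum(rng.normal(mu, sd), 0.0)

    features = None
    if with_features:
        centres = _feature_means(config)
        features = centres[state_idx] + rng.normal(0.0, 1.0, size=(n, config.n_features))

    wear = np.ones(n, dtype=bool)
    stationary = np.zeros(n, dtype=bool)
    n_gaps = rng.poisson(config.nonwear_gaps_per_day)
    per_min = int(round(60.0 / epoch_s))
    for _ in range(n_gaps):
        length_min = rng.uniform(config.nonwear_gap_min_minutes, config.nonwear_gap_max_minutes)
        length_ep = int(round(length_min * per_min))
        start = int(rng.integers(0, max(n - length_ep, 1)))
        sl = slice(start, min(start + length_ep, n))
        wear[sl] = False
        stationary[sl] = True
        vm[sl] = np.maximum(rng.normal(1.0, 0.5, size=sl.stop - sl.start), 0.0)

    start0 = np.datetime64(pd.Timestamp(schedule.day), "ns")
    starts = start0 + (np.arange(n) * int(epoch_s * 1e9)).astype("timedelta64[ns]")
    return EpochSeries(
        epoch_length_s=epoch_s,
        start=starts,
        vm_mg=vm,
        wear=wear,
        stationary=stationary,
        label=states,
        features=features,
    )


def _raw_day(
    schedule: BehaviourSchedule,
    config: GeneratorConfig,
    rng: np.random.Generator,
    day_vm_target: float,
    calibration_error: tuple[np.ndarray, np.ndarray] | None = None,
    span: tuple[float, float] | None = None,
) -> RawTrace:
    """Raw-tier triaxial signal for (part of) one scheduled day.

    Construction: a gravity unit vector precessing slowly (defeating
    stationarity tests while leaving the norm unchanged), scaled by a
    radial oscillation 1 + A sin(2 pi f t) whose amplitude encodes the
    state's target ENMO mean exactly (mean of max(0, A sin) = A / pi),
    plus noise perpendicular to gravity (second-order ENMO effect only).
    Non-wear is synthesised separately as a fixed orientation with a few
    mg of sensor noise.
    """
    rate = config.raw_rate_hz
    lo_h, hi_h = span if span else (0.0, 24.0)
    n = int(round((hi_h - lo_h) * 3600 * rate))
    t_h = lo_h + np.arange(n) / rate / 3600.0
    t_s = (t_h - lo_h) * 3600.0

    bounds = np.asarray([seg[1] for seg in schedule.segments])
    seg_idx = np.searchsorted(bounds, t_h, side="right").clip(max=len(schedule.segments) - 1)
    seg_states = np.asarray([STATES.index(seg[2]) for seg in schedule.segments])
    state_idx = seg_states[seg_idx]

    base = config.state_vm_distributions
    mu = np.asarray([base[s][0] for s in STATES])
    frac = np.bincount(state_idx, minlength=len(STATES)) / n
    expected = float(frac @ mu)
    scale = max(day_vm_target, 0.5) / expected

    state_freq = np.asarray([2.0, 1.0, 2.8, 0.3, 0.1])  # Hz per state
    amp = np.pi * mu * scale / 1000.0  # g; mean truncated ENMO = amp / pi
    phase = rng.uniform(0, 2 * np.pi)
    radial = 1.0 + amp[state_idx] * np.sin(2 * np.pi * state_freq[state_idx] * t_s + phase)

    # precessing orientation: polar/azimuth drift with per-segment phase
    alpha = 1.0 + 0.2 * np.sin(2 * np.pi * t_s / 60.0 + rng.uniform(0, 2 * np.pi))
    beta = 2 * np.pi * t_s / 120.0 + rng.uniform(0, 2 * np.pi)
    d = np.column_stack(
        [np.sin(alpha) * np.cos(beta), np.sin(alpha) * np.sin(beta), np.cos(alpha)]
    )
    # orthonormal frame perpendicular to d for noise injection
    ref = np.zeros_like(d)
    ref[:, 2] = 1.0
    u = np.cross(d, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    sigma = config.raw_noise_mg / 1000.0
    noise = sigma * (rng.normal(size=(n, 1)) * u + rng.normal(size=(n, 1)) * v)
    xyz = d * radial[:, None] + noise

    # non-wear gaps: fixed orientation with a few mg of sensor noise
    wear_truth = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(config.nonwear_gaps_per_day * (hi_h - lo_h) / 24.0)
    for _ in range(n_gaps):
        length_min = rng.uniform(config.nonwear_gap_min_minutes, config.nonwear_gap_max_minutes)
        length = int(round(length_min * 60 * rate))
        g0 = int(rng.integers(0, max(n - length, 1)))
        sl = slice(g0, min(g0 + length, n))
        still = d[g0] / np.linalg.norm(d[g0])
        m = sl.stop - sl.start
        xyz[sl] = still[None, :] + rng.normal(0.0, 0.003, size=(m, 3))
        wear_truth[sl] = False

    if calibration_error is not None:
        offset, gain = calibration_error
        xyz = xyz / gain + offset  # what a miscalibrated device records

    start = pd.Timestamp(schedule.day) + pd.Timedelta(hours=lo_h)
    t = (
        np.datetime64(start, "ns")
        + (np.arange(n) * int(1e9 / rate)).astype("timedelta64[ns]")
    )
    trace = RawTrace(
        device_id="SYN",
        sample_rate_hz=rate,
        start_time=start,
        t=t,
        xyz=xyz,
        dynamic_range_g=8.0,
    )
    trace.wear_truth = wear_truth  # per-sample truth mask for recovery tests
    return trace


def synthesize_signal(
    schedule: BehaviourSchedule,
    config: GeneratorConfig,
    seed: int | None = None,
    day_vm_mg: float | None = None,
    tier: str | None = None,
    rng: np.random.Generator | None = None,
    with_features: bool = True,
    calibration_error: tuple[np.ndarray, np.ndarray] | None = None,
    span_h: tuple[float, float] | None = None,
) -> RawTrace | EpochSeries:
    """Synthesise one scheduled day at the requested fidelity tier.

    ``day_vm_mg`` is the day's target mean ENMO (defaults to the cohort
    day-type level); state emission intensities are rescaled so the
    schedule-implied expected daily mean equals it. Raw tier refuses
    spans beyond ``max_raw_span_h`` — it exists to validate
    preprocessing on short spans, not to simulate cohorts at 100 Hz.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tier = tier or config.tier
    if day_vm_mg is None:
        day_vm_mg = config.daytype_vm_mg[schedule.day_type]
    if tier == "epoch":
        return _epoch_day(schedule, config, rng, day_vm_mg, with_features=with_features)
    if tier == "raw":
        lo, hi = span_h if span_h else (0.0, 24.0)
        if hi - lo > config.max_raw_span_h:
            raise ValueError(
                f"raw tier span {hi - lo:g} h exceeds max_raw_span_h="
                f"{config.max_raw_span_h:g}; raise the limit or use the epoch "
                "tier for cohort-scale runs"
            )
        return _raw_day(
            schedule, config, rng, day_vm_mg, calibration_error=calibration_error, span=span_h
        )
    raise ValueError(f"unknown tier {tier!r}")


def generate_participant_epochs(
    participant: ParticipantRecord,
    truth_row: pd.Series,
    config: GeneratorConfig,
    start_date: dt.date | None = None,
    partial_first_day: bool = True,
    with_features: bool = True,
) -> EpochSeries:
    """Epoch-tier record for one participant: partial fitting day + full days.

    The fitting-visit day starts at noon (exercising the partial-day
    exclusion rule) followed by ``config.wear_days`` complete days.
    Deterministic given the config seed and participant id.
    """
    pid_num = int("".join(c for c in participant.id if c.isdigit()) or 0)
    rng = np.random.default_rng([config.seed, 7919, pid_num])
    if start_date is None:
        start_date = dt.date(2016, 11, 7) + dt.timedelta(days=int(rng.integers(0, 7)))

    days = []
    n_days = config.wear_days + (1 if partial_first_day else 0)
    for k in range(n_days):
        day = start_date + dt.timedelta(days=k)
        is_d = bool(
            participant.dialysis_weekdays and day.weekday() in participant.dialysis_weekdays
        )
        ty = "dialysis" if is_d else "non-dialysis"
        truth_hours = {s: truth_row[f"hours_{s}_{ty}"] for s in STATES}
        sched = generate_schedule(participant, day, config, truth_hours=truth_hours, rng=rng)
        target = float(truth_row[f"vm_{ty}"]) + rng.normal(0.0, config.day_vm_sd)
        day_cfg = config
        if k == 0 and partial_first_day:
            # no gaps on the fitting day: trimming at noon could truncate one
            # below the detection threshold, and the day is excluded anyway
            day_cfg = config.replace(nonwear_gaps_per_day=0.0)
        ep = _epoch_day(sched, day_cfg, rng, max(target, 0.5), with_features=with_features)
        if k == 0 and partial_first_day:
            keep = pd.DatetimeIndex(ep.start).hour >= 12
            ep = EpochSeries(
                epoch_length_s=ep.epoch_length_s,
                start=ep.start[keep],
                vm_mg=ep.vm_mg[keep],
                wear=ep.wear[keep],
                stationary=ep.stationary[keep],
                label=ep.label[keep],
                features=ep.features[keep] if ep.features is not None else None,
            )
        days.append(ep)
    return _concat_epochs(days)


def _concat_epochs(parts: list[EpochSeries]) -> EpochSeries:
    return EpochSeries(
        epoch_length_s=parts[0].epoch_length_s,
        start=np.concatenate([p.start for p in parts]),
        vm_mg=np.concatenate([p.vm_mg for p in parts]),
        wear=np.concatenate([p.wear for p in parts]),
        stationary=np.concatenate([p.stationary for p in parts]),
        label=np.concatenate([p.label for p in parts]),
        features=np.concatenate([p.features for p in parts])
        if parts[0].features is not None
        else None,
    )


# ---------------------------------------------------------------------------
# Questionnaires


def _ordinal_from_latent(latent: float, n_levels: int, rng) -> int:
    """Map a standard-normal latent to an ordinal level via quantile cuts."""
    cuts = [_phi_inv((k + 1) / n_levels) for k in range(n_levels - 1)]
    return 1 + int(np.searchsorted(cuts, latent))


def _phi_inv(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def generate_questionnaires(
    participant: ParticipantRecord,
    true_activity: float,
    config: GeneratorConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    activity_scale: tuple[float, float] = (15.5, 6.0),
) -> tuple[KCCQResponse, EQ5DResponse]:
    """Item responses whose limitation scores rank-correlate with activity.

    A shared latent mixes the standardized true activity with noise at
    ``questionnaire_strength``; each item discretises an item-level latent
    into its ordinal scale, with higher activity giving better (higher
    KCCQ, lower EQ-5D disability) levels.
    """
    if true_activity <= 0:
        raise ValueError("true_activity must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    s = config.questionnaire_strength
    z = (true_activity - activity_scale[0]) / activity_scale[1]
    mix = math.sqrt(max(1.0 - s * s, 0.0))

    def item_latent() -> float:
        return s * z + mix * rng.normal()

    kccq_kw = {}
    for domain, (n_items, max_level) in KCCQ_DOMAINS.items():
        kccq_kw[domain] = [
            _ordinal_from_latent(item_latent(), max_level, rng) for _ in range(n_items)
        ]
    kccq = KCCQResponse(**kccq_kw)

    def eq_level() -> int:
        # higher activity -> lower disability level
        return 4 - _ordinal_from_latent(item_latent(), 3, rng)

    vas = int(np.clip(round(60 + 20 * (s * z + mix * rng.normal())), 1, 100))
    eq5d = EQ5DResponse(
        mobility=eq_level(),
        self_care=eq_level(),
        usual_activities=eq_level(),
        pain_discomfort=int(rng.integers(1, 4)),
        anxiety_depression=int(rng.integers(1, 4)),
        vas=vas,
    )
    return kccq, eq5d


# ---------------------------------------------------------------------------
# Control pools

CONTROL_SCENARIOS = {
    "healthy": {
        "vm_mg": 28.1,
        "n": 318,
        "age_mean": 64.1,
        "age_sd": 9.5,
        "female_fraction": 110 / 318,
        "profile": {"walking": 2.6, "light_tasks": 1.2, "moderate": 1.0, "sedentary": 10.7, "sleep": 8.5},
    },
    "cvd_dm": {
        "vm_mg": 23.4,
        "n": 297,
        "age_mean": 65.0,
        "age_sd": 8.8,
        "female_fraction": 100 / 297,
        "profile": {"walking": 2.2, "light_tasks": 1.0, "moderate": 0.8, "sedentary": 11.5, "sleep": 8.5},
    },
    "heart_failure": {
        "vm_mg": 22.9,
        "n": 172,
        "age_mean": 67.0,
        "age_sd": 6.6,
        "female_fraction": 37 / 172,
        "profile": {"walking": 2.2, "light_tasks": 1.0, "moderate": 0.8, "sedentary": 11.5, "sleep": 8.5},
    },
}


def generate_control_pool(
    scenario: str,
    n: int | None = None,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    control_sd_mg: float = 5.0,
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Draw a matched-control pool for one comparison scenario.

    Controls have no dialysis schedule, conventional night sleep, a
    recorded wear season, and true mean ENMO centred on the scenario
    level (healthy 28.1 mg, prior CVD/diabetes 23.4 mg, heart failure
    22.9 mg). Returns ``(records, truth)`` in the cohort truth layout,
    with both day-type columns equal (controls have no dialysis days).
    """
    if scenario not in CONTROL_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    sc = CONTROL_SCENARIOS[scenario]
    if n is None:
        n = sc["n"]
    if n <= 0:
        raise ValueError("n must be positive")
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng([seed if seed is not None else config.seed, 211])

    ages = _truncated_normal(rng, sc["age_mean"], sc["age_sd"], 45.0, 75.0, n)
    female = _exact_count_mask(rng, n, sc["female_fraction"])
    vm = np.maximum(rng.normal(sc["vm_mg"], control_sd_mg, size=n), 2.0)
    seasons = [SEASONS[i] for i in rng.integers(0, 4, size=n)]

    records, rows = [], []
    for i in range(n):
        pid = f"C{scenario[:2].upper()}{i + 1:04d}"
        records.append(
            ParticipantRecord(
                id=pid,
                age=float(ages[i]),
                sex="female" if female[i] else "male",
                dialysis_weekdays=(),
                wear_season=seasons[i],
                cvd_or_dm=scenario in ("cvd_dm", "heart_failure"),
            )
        )
        row = {
            "id": pid,
            "age": float(ages[i]),
            "sex": "female" if female[i] else "male",
            "leg_weakness": False,
            "slot": None,
            "vm_dialysis": float(vm[i]),
            "vm_non-dialysis": float(vm[i]),
            "vm_overall": float(vm[i]),
        }
        rel = float(vm[i]) / sc["vm_mg"]
        for ty in ("dialysis", "non-dialysis"):
            hours = _participant_hours(sc["profile"], rel)
            for s in STATES:
                row[f"hours_{s}_{ty}"] = hours[s]
        rows.append(row)
    return records, pd.DataFrame(rows)
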