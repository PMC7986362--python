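"""Wear-time quality control and dialysis-aware time-of-day imputation.

Non-wear is an extended stationary episode (device off the wrist); the
cohort's inclusion criterion — "excellent wear" — demands at least 72 h
of worn data with every 1-h clock period covered, assessed here with
hourly coverage required separately on dialysis and non-dialysis days.
Missing segments are imputed from the average of worn data at the same
clock minute on other days of the same day type, so a dialysis-session
gap is never filled with non-dialysis activity (and vice versa).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import STATES
from .raw_io import EpochSeries, ParticipantRecord

__all__ = [
    "MinuteGrid",
    "WearReport",
    "detect_nonwear",
    "label_day_types",
    "build_minute_grid",
    "assess_wear",
    "impute_minute_grid",
]

DAY_TYPES = ("dialysis", "non-dialysis", "excluded")


@dataclass
class MinuteGrid:
    """Per-participant (days x 1440) matrices of vm, state, wear and imputation flags.

    The pipeline's central exchange object: one row per calendar day, one
    column per clock minute. ``vm`` is in mg with NaN for missing; ``state``
    holds behaviour-state names (or None); ``imputed`` marks minutes filled
    by time-of-day imputation.
    """

    participant_id: str
    days: list[tuple[dt.date, str]]
    vm: np.ndarray
    state: np.ndarray
    wear: np.ndarray
    imputed: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.vm.shape, self.state.shape, self.wear.shape, self.imputed.shape}
        if len(shapes) != 1 or self.vm.shape != (len(self.days), 1440):
            raise ValueError("matrices must all be (n_days, 1440)")
        if np.nanmin(self.vm, initial=0.0) < -1e-9:
            raise ValueError("vm must be non-negative where present")
        if (self.imputed & self.wear).any():
            raise ValueError("imputed minutes cannot be worn minutes")

    def day_mask(self, day_type: str) -> np.ndarray:
        return np.asarray([ty == day_type for _, ty in self.days], dtype=bool)

    @property
    def included_mask(self) -> np.ndarray:
        return np.asarray([ty != "excluded" for _, ty in self.days], dtype=bool)


@dataclass
class WearReport:
    participant_id: str
    total_wear_h: float
    wear_h_by_daytype: dict[str, float]
    hourly_coverage: dict[str, np.ndarray] = field(default_factory=dict)
    excellent_overall: bool = False
    excellent_both_daytypes: bool = False


def detect_nonwear(epochs: EpochSeries, min_gap_min: float = 60.0) -> EpochSeries:
    """Flag contiguous stationary runs of at least ``min_gap_min`` as non-wear.

    Requires the stationarity indicator attached by preprocessing (or the
    generator). Shorter stationary runs stay worn — rests and naps are
    movement-poor but still on-wrist.
    """
    if epochs.stationary is None:
        raise ValueError("epochs must carry a stationarity indicator")
    wear = np.ones(len(epochs), dtype=bool)
    min_epochs = int(np.ceil(min_gap_min * 60.0 / epochs.epoch_length_s))
    stat = epochs.stationary
    i = 0
    n = len(stat)
    while i < n:
        if stat[i]:
            j = i
            while j < n and stat[j]:
                j += 1
            if j - i >= min_epochs:
                wear[i:j] = False
            i = j
        else:
            i += 1
    return EpochSeries(
        epoch_length_s=epochs.epoch_length_s,
        start=epochs.start,
        vm_mg=epochs.vm_mg,
        wear=wear,
        stationary=epochs.stationary,
        label=epochs.label,
        features=epochs.features,
    )


def label_day_types(
    days: list[dt.date],
    participant: ParticipantRecord,
    recorded_minutes: list[int] | None = None,
    full_day_minutes: int = 1440,
) -> list[str]:
    """Classify each calendar day as dialysis / non-dialysis / excluded.

    A day whose weekday is in the participant's treatment pattern is a
    dialysis day; controls (empty pattern) get all non-dialysis. Partial
    first and last days (device fitting/return) are excluded from every
    summary.
    """
    types = []
    for day in days:
        if participant.dialysis_weekdays and day.weekday() in participant.dialysis_weekdays:
            types.append("dialysis")
        else:
            types.append("non-dialysis")
    if recorded_minutes is not None and types:
        if recorded_minutes[0] < full_day_minutes:
            types[0] = "excluded"
        if recorded_minutes[-1] < full_day_minutes:
            types[-1] = "excluded"
    return types


def build_minute_grid(
    epochs: EpochSeries,
    participant: ParticipantRecord,
    states: tuple[str, ...] = STATES,
) -> MinuteGrid:
    """Aggregate 30-s epochs onto the (day x 1440 clock minutes) grid.

    Per-minute vm is the mean over the minute's worn epochs; the minute is
    worn only when all of its epochs are recorded and worn. Per-minute
    state is the majority of the minute's epoch labels, ties resolved to
    the earlier epoch's label.
    """
    idx = pd.DatetimeIndex(epochs.start)
    dates = idx.normalize()
    uniq_dates = dates.unique().sort_values()
    date_pos = {d: k for k, d in enumerate(uniq_dates)}
    n_days = len(uniq_dates)
    ep_per_min = max(1, int(round(60.0 / epochs.epoch_length_s)))

    day_i = np.asarray([date_pos[d] for d in dates])
    min_i = idx.hour * 60 + idx.minute

    vm = np.full((n_days, 1440), np.nan)
    state = np.full((n_days, 1440), None, dtype=object)
    wear = np.zeros((n_days, 1440), dtype=bool)
    recorded = np.zeros((n_days, 1440), dtype=np.int16)
    vm_sum = np.zeros((n_days, 1440))
    worn_ct = np.zeros((n_days, 1440), dtype=np.int16)

    np.add.at(recorded, (day_i, min_i), 1)
    w = epochs.wear
    np.add.at(vm_sum, (day_i[w], min_i[w]), epochs.vm_mg[w])
    np.add.at(worn_ct, (day_i[w], min_i[w]), 1)
    full = (recorded == ep_per_min) & (worn_ct == ep_per_min)
    wear[full] = True
    with np.errstate(invalid="ignore"):
        vm[full] = vm_sum[full] / worn_ct[full]

    if epochs.label is not None:
        # majority vote per minute; ties go to the earliest epoch's label
        lut = {s: i for i, s in enumerate(states)}
        lab_i = np.asarray([lut[s] for s in epochs.label], dtype=int)
        counts = np.zeros((n_days, 1440, len(states)), dtype=np.int8)
        np.add.at(counts, (day_i[w], min_i[w], lab_i[w]), 1)
        first = np.full((n_days, 1440), -1, dtype=np.int8)
        order = np.argsort(idx.values, kind="stable")
        for k in order[::-1]:
            if w[k]:
                first[day_i[k], min_i[k]] = lab_i[k]
        maxc = counts.max(axis=2)
        n_at_max = (counts == maxc[:, :, None]).sum(axis=2)
        winner = counts.argmax(axis=2)
        tie = (n_at_max > 1) & (maxc > 0)
        winner[tie] = first[tie]
        has = full & (maxc > 0)
        state[has] = np.asarray(states, dtype=object)[winner[has]]

    recorded_per_day = (recorded > 0).sum(axis=1)
    day_types = label_day_types(
        [d.date() for d in uniq_dates], participant, recorded_minutes=list(recorded_per_day)
    )
    return MinuteGrid(
        participant_id=participant.id,
        days=[(d.date(), ty) for d, ty in zip(uniq_dates, day_types)],
        vm=vm,
        state=state,
        wear=wear,
        imputed=np.zeros((n_days, 1440), dtype=bool),
    )


def assess_wear(grid: MinuteGrid, min_hours: float = 72.0) -> WearReport:
    """Evaluate the excellent-wear inclusion criterion.

    ``excellent_overall``: total worn time >= 72 h and every 1-h clock bin
    has at least one worn minute somewhere in the record.
    ``excellent_both_daytypes``: additionally the hourly coverage holds
    within the dialysis-day subset and the non-dialysis-day subset
    separately (an empty subset — e.g. controls — is vacuously covered).
    """
    inc = grid.included_mask
    wear = grid.wear[inc]
    total_h = float(wear.sum()) / 60.0
    by_hour = wear.reshape(-1, 24, 60).any(axis=(0, 2)) if len(wear) else np.zeros(24, bool)

    coverage: dict[str, np.ndarray] = {"overall": by_hour}
    both = True
    wear_by_type: dict[str, float] = {}
    for ty in ("dialysis", "non-dialysis"):
        sub = grid.wear[grid.day_mask(ty)]
        wear_by_type[ty] = float(sub.sum()) / 60.0
        if len(sub):
            cov = sub.reshape(-1, 24, 60).any(axis=(0, 2))
            coverage[ty] = cov
            both = both and bool(cov.all())
        else:
            coverage[ty] = np.zeros(24, dtype=bool)
    excellent_overall = total_h >= min_hours and bool(by_hour.all())
    return WearReport(
        participant_id=grid.participant_id,
        total_wear_h=total_h,
        wear_h_by_daytype=wear_by_type,
        hourly_coverage=coverage,
        excellent_overall=excellent_overall,
        excellent_both_daytypes=excellent_overall and both,
    )


def impute_minute_grid(grid: MinuteGrid, states: tuple[str, ...] = STATES) -> MinuteGrid:
    """Fill unworn minutes from same-clock-minute donors within day type.

    Each missing minute's vm becomes the mean of worn vm at the same
    clock minute on the other days of the same day type; its state the
    modal worn state there. Minutes with no donor anywhere stay missing
    and are excluded from summaries. Worn minutes are never altered, so
    the operation is the identity on complete grids.
    """
    vm = grid.vm.copy()
    state = grid.state.copy()
    imputed = grid.imputed.copy()
    lut = {s: i for i, s in enumerate(states)}
    for ty in ("dialysis", "non-dialysis"):
        rows = np.flatnonzero(grid.day_mask(ty))
        if len(rows) == 0:
            continue
        sub_wear = grid.wear[rows]  # (d, 1440)
        sub_vm = grid.vm[rows]
        donor_ct = sub_wear.sum(axis=0)
        with np.errstate(invalid="ignore"):
            donor_mean = np.where(
                donor_ct > 0,
                np.nansum(np.where(sub_wear, sub_vm, 0.0), axis=0) / np.maximum(donor_ct, 1),
                np.nan,
            )
        # modal donor state per minute (first-in-STATES order breaks ties)
        st_counts = np.zeros((1440, len(states)), dtype=np.int32)
        flat = pd.Series(grid.state[rows].ravel())
        st_idx = flat.map(lut).fillna(-1).to_numpy(dtype=int).reshape(len(rows), 1440)
        mask = sub_wear & (st_idx >= 0)
        minute_cols = np.broadcast_to(np.arange(1440), (len(rows), 1440))
        np.add.at(st_counts, (minute_cols[mask], st_idx[mask]), 1)
        has_state = st_counts.sum(axis=1) > 0
        modal = np.asarray(states, dtype=object)[st_counts.argmax(axis=1)]
        for r in rows:
            missing = ~grid.wear[r]
            fillable = missing & (donor_ct > 0)
            vm[r, fillable] = donor_mean[fillable]
            imputed[r, fillable] = True
            st_fill = fillable & has_state
            state[r, st_fill] = modal[st_fill]
    return MinuteGrid(
        participant_id=grid.participant_id,
        days=list(grid.days),
        vm=vm,
        state=state,
        wear=grid.wear.copy(),
        imputed=imputed,
    )
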