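"""On-disk formats: raw traces, epoch series, cohort tables, minute grids, model bundles.

The raw-trace format is a plain CSV dialect (``t,x,y,z`` with ISO-8601 or
epoch-seconds timestamps, in gravity units) with ``#``-prefixed metadata
header lines; proprietary device binaries are out of scope. All timestamps
are timezone-naive local clock time, because day structure (dialysis slots,
time-of-day profiles) is defined on the wall clock.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "RawTrace",
    "EpochSeries",
    "ParticipantRecord",
    "WEEKDAY_NAMES",
    "read_raw_trace",
    "write_raw_trace",
    "read_epoch_series",
    "write_epoch_series",
    "read_cohort_table",
    "write_cohort_table",
]

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class FormatError(ValueError):
    """File does not follow the declared dialect (e.g. missing header)."""


class IntegrityError(ValueError):
    """File parses but violates an invariant (duplicate id, bad row, ...)."""


@dataclass
class RawTrace:
    """Timestamped triaxial acceleration in gravity units.

    ``t`` is a datetime64[ns] array (strictly increasing, tz-naive);
    ``xyz`` is an (n, 3) float array bounded by ``dynamic_range_g``.
    """

    device_id: str
    sample_rate_hz: float
    start_time: pd.Timestamp
    t: np.ndarray
    xyz: np.ndarray
    dynamic_range_g: float = 8.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[ns]")
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if len(self.t) != len(self.xyz):
            raise ValueError("t and xyz lengths differ")
        if len(self.t) > 1 and not (np.diff(self.t.astype("int64")) > 0).all():
            bad = int(np.flatnonzero(np.diff(self.t.astype("int64")) <= 0)[0]) + 1
            raise IntegrityError(f"timestamps not strictly increasing at sample {bad}")
        if len(self.xyz) and np.abs(self.xyz).max() > self.dynamic_range_g + 1e-9:
            raise ValueError("samples exceed dynamic range")

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class EpochSeries:
    """Fixed-length epoch summaries of a trace.

    ``start`` are epoch start times, ``vm_mg`` the mean truncated vector
    magnitude (ENMO) in milligravity, ``wear`` the wear mask, ``stationary``
    an optional stationarity indicator, ``label`` optional behaviour-state
    codes and ``features`` an optional (n, d) matrix.
    """

    epoch_length_s: float
    start: np.ndarray
    vm_mg: np.ndarray
    wear: np.ndarray
    stationary: np.ndarray | None = None
    label: np.ndarray | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        self.start = np.asarray(self.start, dtype="datetime64[ns]")
        self.vm_mg = np.asarray(self.vm_mg, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        n = len(self.start)
        for name in ("vm_mg", "wear", "stationary", "label"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if len(self.features) != n:
                raise ValueError("features length mismatch")
        if n and np.nanmin(self.vm_mg) < -1e-9:
            raise ValueError("vm_mg must be non-negative")

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class ParticipantRecord:
    """Demographics, clinical flags, dialysis schedule and questionnaire scores.

    Optional clinical flags are tri-state: True / False / None (missing) —
    missingness is data, never silently defaulted. ``dialysis_weekdays``
    is empty for controls.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    dialysis_weekdays: tuple[int, ...] = ()  # 0 = Monday
    slot: str | None = None  # "morning" | "afternoon"
    leg_weakness: bool | None = None
    breathlessness: bool | None = None
    listed_transplant: bool | None = None
    arrhythmia: bool | None = None
    cvd_or_dm: bool | None = None
    wear_season: str | None = None  # "winter" | "spring" | "summer" | "autumn"
    kccq: object | None = None
    eq5d: object | None = None

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 110):
            raise ValueError(f"age {self.age} outside [18, 110]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.dialysis_weekdays = tuple(sorted(int(d) for d in self.dialysis_weekdays))
        if any(not 0 <= d <= 6 for d in self.dialysis_weekdays):
            raise ValueError("weekday indices must be 0..6")

    @property
    def on_dialysis(self) -> bool:
        return len(self.dialysis_weekdays) > 0


# ---------------------------------------------------------------------------
# Raw traces


def write_raw_trace(trace: RawTrace, path: str | Path, precision: int = 6) -> Path:
    """Write a trace as ``#``-headed CSV; re-readable by :func:`read_raw_trace`.

    Acceleration values are written with ``precision`` decimals, so the
    round-trip error is bounded by half an ulp of the fixed-precision text
    (5e-7 g at the default 6 decimals).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# device_id: {trace.device_id}\n")
        fh.write(f"# sample_rate_hz: {trace.sample_rate_hz!r}\n")
        fh.write(f"# start_time: {pd.Timestamp(trace.start_time).isoformat()}\n")
        fh.write(f"# dynamic_range_g: {trace.dynamic_range_g!r}\n")
        fh.write(f"# calibrated: {str(trace.calibrated).lower()}\n")
        fh.write("t,x,y,z\n")
        ts = pd.DatetimeIndex(trace.t)
        fmt = f"%.{precision}f"
        for i in range(len(ts)):
            x, y, z = trace.xyz[i]
            fh.write(f"{ts[i].isoformat()},{fmt % x},{fmt % y},{fmt % z}\n")
    return path


def _read_header(lines: list[str]) -> dict[str, str]:
    meta = {}
    for ln in lines:
        body = ln[1:].strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_raw_trace(path: str | Path, dialect: str = "csv") -> RawTrace:
    """Read a ``#``-headed ``t,x,y,z`` CSV trace.

    Raises :class:`FormatError` when the metadata header is missing and
    :class:`IntegrityError` (naming the first offending row) for
    unparseable fields or non-monotonic timestamps.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    header_lines: list[str] = []
    data_lines: list[str] = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                header_lines.append(ln)
            elif ln.strip():
                data_lines.append(ln)
    meta = _read_header(header_lines)
    required = {"device_id", "sample_rate_hz", "start_time"}
    if not required.issubset(meta):
        raise FormatError(f"missing header fields {sorted(required - set(meta))} in {path}")
    if not data_lines or data_lines[0].strip() != "t,x,y,z":
        raise FormatError(f"missing 't,x,y,z' column header in {path}")

    n = len(data_lines) - 1
    t = np.empty(n, dtype="datetime64[ns]")
    xyz = np.empty((n, 3), dtype=float)
    for i, ln in enumerate(data_lines[1:]):
        parts = ln.strip().split(",")
        if len(parts) != 4:
            raise IntegrityError(f"row {i + 1}: expected 4 fields, got {len(parts)}")
        try:
            try:
                t[i] = np.datetime64(parts[0])
            except ValueError:
                # epoch-seconds fallback
                t[i] = pd.Timestamp(float(parts[0]), unit="s").to_datetime64()
            xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except (ValueError, TypeError) as exc:
            raise IntegrityError(f"row {i + 1}: unparseable field ({exc})") from None
    if n > 1:
        dt = np.diff(t.astype("int64"))
        if not (dt > 0).all():
            bad = int(np.flatnonzero(dt <= 0)[0]) + 2  # 1-based row of the offender
            raise IntegrityError(f"non-monotonic timestamp at row {bad}")
    return RawTrace(
        device_id=meta["device_id"],
        sample_rate_hz=float(meta["sample_rate_hz"]),
        start_time=pd.Timestamp(meta["start_time"]),
        t=t,
        xyz=xyz,
        dynamic_range_g=float(meta.get("dynamic_range_g", 8.0)),
        calibrated=meta.get("calibrated", "false") == "true",
    )


# ---------------------------------------------------------------------------
# Epoch series


def write_epoch_series(series: EpochSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"start": pd.DatetimeIndex(series.start).map(lambda x: x.isoformat())})
    df["vm_mg"] = series.vm_mg
    df["wear"] = series.wear.astype(int)
    df["stationary"] = (
        series.stationary.astype(int) if series.stationary is not None else ""
    )
    df["label"] = series.label if series.label is not None else ""
    if series.features is not None:
        for j in range(series.features.shape[1]):
            df[f"f{j}"] = series.features[:, j]
    with open(path, "w") as fh:
        fh.write(f"# epoch_length_s: {series.epoch_length_s!r}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_epoch_series(path: str | Path) -> EpochSeries:
    path = Path(path)
    with open(path) as fh:
        header = []
        pos = fh.tell()
        while True:
            ln = fh.readline()
            if ln.startswith("#"):
                header.append(ln)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, keep_default_na=False, na_values=[])
    meta = _read_header(header)
    if "epoch_length_s" not in meta:
        raise FormatError(f"missing epoch_length_s header in {path}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    has_stat = "stationary" in df.columns and not (df["stationary"].astype(str) == "").all()
    has_label = "label" in df.columns and not (df["label"].astype(str) == "").all()
    return EpochSeries(
        epoch_length_s=float(meta["epoch_length_s"]),
        start=pd.to_datetime(df["start"]).to_numpy(),
        vm_mg=df["vm_mg"].to_numpy(dtype=float),
        wear=df["wear"].to_numpy(dtype=int).astype(bool),
        stationary=df["stationary"].to_numpy(dtype=int).astype(bool) if has_stat else None,
        label=df["label"].to_numpy(dtype=object) if has_label else None,
        features=df[sorted(feat_cols, key=lambda c: int(c[1:]))].to_numpy(dtype=float)
        if feat_cols
        else None,
    )


# ---------------------------------------------------------------------------
# Cohort tables

_BOOL_COLS = ("leg_weakness", "breathlessness", "listed_transplant", "arrhythmia", "cvd_or_dm")


def _fmt_tristate(v: bool | None) -> str:
    return "" if v is None else str(bool(v)).lower()


def _parse_tristate(v: str, col: str, row: int) -> bool | None:
    v = v.strip().lower()
    if v == "":
        return None
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise IntegrityError(f"row {row}: bad boolean {v!r} in column {col!r}")


def write_cohort_table(records: list[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "dialysis_weekdays": "|".join(WEEKDAY_NAMES[d] for d in r.dialysis_weekdays),
                "slot": r.slot or "",
                "wear_season": r.wear_season or "",
                **{c: _fmt_tristate(getattr(r, c)) for c in _BOOL_COLS},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> list[ParticipantRecord]:
    """Read a participant table; optional fields stay missing, never defaulted."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    dupes = df["id"][df["id"].duplicated()]
    if len(dupes):
        raise IntegrityError(f"duplicate participant id {dupes.iloc[0]!r}")
    name_to_idx = {n: i for i, n in enumerate(WEEKDAY_NAMES)}
    records = []
    for i, row in df.iterrows():
        wk = row.get("dialysis_weekdays", "").strip()
        try:
            weekdays = tuple(name_to_idx[w] for w in wk.split("|")) if wk else ()
        except KeyError as exc:
            raise IntegrityError(f"row {i + 1}: unknown weekday {exc}") from None
        records.append(
            ParticipantRecord(
                id=row["id"],
                age=float(row["age"]),
                sex=row["sex"],
                dialysis_weekdays=weekdays,
                slot=row.get("slot", "").strip() or None,
                wear_season=row.get("wear_season", "").strip() or None,
                **{c: _parse_tristate(row.get(c, ""), c, i + 1) for c in _BOOL_COLS},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Minute grids (the type lives in wear_qc; IO here for one-stop persistence)


def write_minute_grid(grid, path: str | Path) -> Path:
    path = Path(path)
    days, _ = grid.vm.shape
    rows = []
    for d in range(days):
        date, day_type = grid.days[d]
        for m in range(1440):
            rows.append(
                (
                    str(date),
                    day_type,
                    m,
                    "" if np.isnan(grid.vm[d, m]) else f"{grid.vm[d, m]:.4f}",
                    "" if grid.state[d, m] is None else grid.state[d, m],
                    int(grid.wear[d, m]),
                    int(grid.imputed[d, m]),
                )
            )
    df = pd.DataFrame(rows, columns=["date", "day_type", "minute", "vm_mg", "state", "wear", "imputed"])
    with open(path, "w") as fh:
        fh.write(f"# participant_id: {grid.participant_id}\n")
        df.to_csv(fh, index=False)
    return path


def read_minute_grid(path: str | Path):
    from .wear_qc import MinuteGrid

    path = Path(path)
    with open(path) as fh:
        header = []
        pos = fh.tell()
        while True:
            ln = fh.readline()
            if ln.startswith("#"):
                header.append(ln)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, dtype={"vm_mg": str, "state": str}, keep_default_na=False, na_values=[])
    meta = _read_header(header)
    day_keys = list(dict.fromkeys(zip(df["date"], df["day_type"])))
    n_days = len(day_keys)
    vm = np.full((n_days, 1440), np.nan)
    state = np.full((n_days, 1440), None, dtype=object)
    wear = np.zeros((n_days, 1440), dtype=bool)
    imputed = np.zeros((n_days, 1440), dtype=bool)
    idx = {k: i for i, k in enumerate(day_keys)}
    d = df
    di = d.apply(lambda r: idx[(r["date"], r["day_type"])], axis=1).to_numpy()
    mi = d["minute"].to_numpy(dtype=int)
    vm_str = d["vm_mg"].astype(str).to_numpy()
    ok = vm_str != ""
    vm[di[ok], mi[ok]] = vm_str[ok].astype(float)
    st = d["state"].astype(str).to_numpy()
    stok = st != ""
    state[di[stok], mi[stok]] = st[stok]
    wear[di, mi] = d["wear"].to_numpy(dtype=int).astype(bool)
    imputed[di, mi] = d["imputed"].to_numpy(dtype=int).astype(bool)
    return MinuteGrid(
        participant_id=meta.get("participant_id", "?"),
        days=[(pd.Timestamp(dt).date(), ty) for dt, ty in day_keys],
        vm=vm,
        state=state,
        wear=wear,
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# Model bundles


def save_model_bundle(model, path: str | Path) -> Path:
    """Persist a trained behaviour model: HMM matrices as CSV, forest via joblib."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "hmm_prior.csv", model.hmm_prior, delimiter=",")
    np.savetxt(path / "hmm_transitions.csv", model.hmm_transitions, delimiter=",")
    np.savetxt(path / "hmm_emission.csv", model.hmm_emission, delimiter=",")
    np.savetxt(path / "oob_confusion.csv", model.forest.oob_confusion_, delimiter=",", fmt="%d")
    with open(path / "meta.json", "w") as fh:
        json.dump({"states": list(model.states)}, fh)
    joblib.dump(model.forest, path / "forest.joblib")
    return path


def load_model_bundle(path: str | Path):
    import joblib

    from .behavior import BehaviourModel

    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    model = BehaviourModel(
        states=tuple(meta["states"]),
        forest=joblib.load(path / "forest.joblib"),
        hmm_prior=np.loadtxt(path / "hmm_prior.csv", delimiter=","),
        hmm_transitions=np.loadtxt(path / "hmm_transitions.csv", delimiter=","),
        hmm_emission=np.loadtxt(path / "hmm_emission.csv", delimiter=","),
    )
    return model
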