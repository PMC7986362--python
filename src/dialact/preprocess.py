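"""Raw-trace preprocessing: stationary detection, autocalibration, ENMO epochs.

Mirrors the Biobank-style accelerometer protocol: find stationary
windows, fit a per-axis offset/gain correction so stationary vectors lie
on the 1-g gravity sphere, then summarise the calibrated signal as
truncated Euclidean-norm-minus-one (ENMO) epoch means in milligravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raw_io import EpochSeries, RawTrace

__all__ = [
    "CalibrationModel",
    "detect_stationary_epochs",
    "fit_calibration",
    "apply_calibration",
    "compute_vm_epochs",
    "resample_trace",
]


@dataclass
class CalibrationModel:
    """Per-axis offset (g) and gain for unit-sphere autocalibration."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    fitted: bool = False
    n_stationary_epochs: int = 0
    residual_before_mg: float = float("nan")
    residual_after_mg: float = float("nan")

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.fitted and not ((self.gain >= 0.5) & (self.gain <= 1.5)).all():
            raise ValueError("fitted gains outside [0.5, 1.5]")

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.offset) * self.gain


def detect_stationary_epochs(
    trace: RawTrace, window_s: float = 10.0, sd_threshold_mg: float = 13.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Find non-overlapping consecutive windows with per-axis sd below threshold.

    Returns ``(starts, ends, means)`` where ``means`` is the (k, 3) per-axis
    mean of each stationary window. An empty trace yields empty arrays.
    """
    w = int(round(window_s * trace.sample_rate_hz))
    n_win = len(trace.t) // w if w > 0 else 0
    if n_win == 0:
        return (
            np.array([], dtype="datetime64[ns]"),
            np.array([], dtype="datetime64[ns]"),
            np.empty((0, 3)),
        )
    xyz = trace.xyz[: n_win * w].reshape(n_win, w, 3)
    sds = xyz.std(axis=1, ddof=0)
    keep = (sds * 1000.0 < sd_threshold_mg).all(axis=1)
    starts = trace.t[np.arange(n_win) * w]
    ends = starts + np.timedelta64(int(window_s * 1e9), "ns")
    return starts[keep], ends[keep], xyz.mean(axis=1)[keep]


def fit_calibration(
    stationary_means: np.ndarray,
    min_epochs: int = 50,
    max_iter: int = 100,
    tol_mg: float = 0.1,
) -> CalibrationModel:
    """Unit-sphere autocalibration from stationary-window axis means.

    Iteratively regresses each axis of the current calibrated points onto
    their projection on the unit sphere, composing offset/gain updates
    until the mean-absolute radius error changes by less than ``tol_mg``.
    Degenerate inputs — fewer than ``min_epochs`` windows, or any axis
    without both positive and negative readings (insufficient sphere
    coverage) — return an unfitted identity model rather than an error.
    """
    pts = np.asarray(stationary_means, dtype=float)
    model = CalibrationModel(n_stationary_epochs=len(pts))
    if len(pts):
        model.residual_before_mg = float(
            np.abs(np.linalg.norm(pts, axis=1) - 1.0).mean() * 1000.0
        )
        model.residual_after_mg = model.residual_before_mg
    if len(pts) < min_epochs:
        return model
    sign_coverage = ((pts > 0.05).any(axis=0) & (pts < -0.05).any(axis=0)).all()
    if not sign_coverage:
        return model

    offset = np.zeros(3)
    gain = np.ones(3)
    prev = np.inf
    for _ in range(max_iter):
        cal = (pts - offset) * gain
        norms = np.linalg.norm(cal, axis=1)
        resid = float(np.abs(norms - 1.0).mean() * 1000.0)
        if abs(prev - resid) < tol_mg:
            break
        prev = resid
        target = cal / norms[:, None]
        for ax in range(3):
            b, a = np.polyfit(cal[:, ax], target[:, ax], 1)
            if b <= 0:
                return model  # pathological geometry; keep identity
            gain[ax] *= b
            offset[ax] = offset[ax] - a / gain[ax]
    cal = (pts - offset) * gain
    resid_after = float(np.abs(np.linalg.norm(cal, axis=1) - 1.0).mean() * 1000.0)
    if resid_after > model.residual_before_mg + 1e-9 or not ((gain >= 0.5) & (gain <= 1.5)).all():
        return model
    resid_after = min(resid_after, model.residual_before_mg)
    model.offset = offset
    model.gain = gain
    model.fitted = True
    model.residual_after_mg = resid_after
    return model


def apply_calibration(trace: RawTrace, model: CalibrationModel) -> RawTrace:
    """Map each sample axis-wise to ``(value - offset) * gain``."""
    return RawTrace(
        device_id=trace.device_id,
        sample_rate_hz=trace.sample_rate_hz,
        start_time=trace.start_time,
        t=trace.t,
        xyz=model.transform(trace.xyz),
        dynamic_range_g=trace.dynamic_range_g,
        calibrated=True,
    )


def compute_vm_epochs(
    trace: RawTrace,
    epoch_s: float = 5.0,
    truncate: bool = True,
    sd_threshold_mg: float = 13.0,
) -> EpochSeries:
    """Summarise a (calibrated) trace as ENMO epoch means in milligravity.

    Per sample, vm = max(0, ||(x,y,z)|| - 1 g) (``truncate=False`` switches
    to the absolute-value variant); the epoch value is the sample mean
    scaled to mg. A partial trailing epoch is dropped. Each epoch also
    carries a stationarity flag (all three axis sds below threshold) used
    downstream for non-wear detection.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    w = int(round(epoch_s * trace.sample_rate_hz))
    n_ep = len(trace.t) // w
    xyz = trace.xyz[: n_ep * w].reshape(n_ep, w, 3)
    norms = np.linalg.norm(xyz, axis=2)
    enmo = np.maximum(norms - 1.0, 0.0) if truncate else np.abs(norms - 1.0)
    vm_mg = enmo.mean(axis=1) * 1000.0
    sds = xyz.std(axis=1, ddof=0)
    stationary = (sds * 1000.0 < sd_threshold_mg).all(axis=1)
    starts = trace.t[np.arange(n_ep) * w]
    return EpochSeries(
        epoch_length_s=epoch_s,
        start=starts,
        vm_mg=vm_mg,
        wear=np.ones(n_ep, dtype=bool),
        stationary=stationary,
    )


def resample_trace(trace: RawTrace, rate_hz: float, max_gap_s: float = 1.0) -> RawTrace:
    """Linearly interpolate onto a uniform grid; gaps > ``max_gap_s`` become NaN.

    Device clocks jitter slightly around the nominal rate; epoching assumes
    a uniform grid, so traces are resampled first. Samples inside long gaps
    are left missing (NaN) rather than invented.
    """
    if len(trace.t) < 2:
        return trace
    t_ns = trace.t.astype("int64")
    step = int(round(1e9 / rate_hz))
    grid = np.arange(t_ns[0], t_ns[-1] + 1, step)
    xyz = np.column_stack(
        [np.interp(grid, t_ns, trace.xyz[:, k]) for k in range(3)]
    )
    # blank out interpolations across long gaps
    gap_idx = np.flatnonzero(np.diff(t_ns) > max_gap_s * 1e9)
    for gi in gap_idx:
        bad = (grid > t_ns[gi]) & (grid < t_ns[gi + 1])
        xyz[bad] = np.nan
    return RawTrace(
        device_id=trace.device_id,
        sample_rate_hz=rate_hz,
        start_time=pd.Timestamp(trace.t[0]),
        t=grid.astype("datetime64[ns]"),
        xyz=xyz,
        dynamic_range_g=trace.dynamic_range_g,
        calibrated=trace.calibrated,
    )
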