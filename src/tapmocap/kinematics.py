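"""Finger-tapping kinematics: from landmark trajectories to trial metrics.

The processing order is fixed: resample to 60 Hz -> trim the first 2 s and
last 1 s -> thumb-index 3D distance (cm) -> [optional cross-system
alignment] -> 4th-order 5 Hz Butterworth low-pass -> central-difference
velocity -> tap-cycle segmentation on distance minima (prominence
>= 0.5 cm, separation >= 0.15 s) -> per-cycle metrics -> trial summary.

A tap cycle runs finger-close to finger-close (consecutive distance
minima). Per cycle: duration ``Dur``, frequency ``Freq = 1/Dur``,
amplitude ``Amp`` (max opening minus the initial close position), and the
extreme opening/closing velocities. The trial summary reports the tap
count, the mean and coefficient of variation of each per-cycle metric,
and the normalized path length (NPL) — total absolute distance variation
per second, a combined amplitude/speed measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .errors import ContractError, QualityError
from .formats import MarkerTrajectory
from .reconstruct import INDEX_TIP, THUMB_TIP, HandTrajectory

_JITTER_TOL = 1e-9  # max allowed deviation from uniform sampling, seconds


@dataclass
class DistanceSignal:
    """Thumb-tip to index-tip 3D distance, uniformly sampled, centimeters."""

    timestamps: np.ndarray  # seconds
    values: np.ndarray  # cm
    rate: float  # Hz
    filtered: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ContractError("timestamps and values must have equal length")
        if len(self.timestamps) >= 2:
            dt = np.diff(self.timestamps)
            if np.ptp(dt) > _JITTER_TOL:
                raise ContractError("distance signal must be uniformly sampled")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class VelocitySignal:
    """Signed rate of change of the distance signal; opening is positive."""

    timestamps: np.ndarray
    values: np.ndarray  # cm/s


@dataclass
class TapCycle:
    """One finger-close-to-finger-close segment and its metrics."""

    start_index: int
    end_index: int
    Dur: float  # s
    Freq: float  # Hz, exactly 1/Dur
    Amp: float  # cm
    MaxOpenVel: float  # cm/s
    MaxCloseVel: float  # cm/s, magnitude


@dataclass
class TrialMetrics:
    """Summary metrics for one hand-trial.

    CVs are sample SD / mean (ddof=1). With zero cycles the means/CVs are
    NaN, TapCount is 0, and NPL is still computed from the whole signal.
    """

    TapCount: int
    Amp_Mean: float
    Amp_CV: float
    Freq_Mean: float
    Freq_CV: float
    MaxOpenVel_Mean: float
    MaxOpenVel_CV: float
    MaxCloseVel_Mean: float
    MaxCloseVel_CV: float
    NPL: float  # cm/s

    #: column order used in metrics CSV output
    FIELDS = (
        "TapCount",
        "Amp_Mean",
        "Amp_CV",
        "Freq_Mean",
        "Freq_CV",
        "MaxOpenVel_Mean",
        "MaxOpenVel_CV",
        "MaxCloseVel_Mean",
        "MaxCloseVel_CV",
        "NPL",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


# ---------------------------------------------------------------------------
# Signal preparation


def resample_uniform(traj, rate: float = 60.0):
    """Resample a hand or marker trajectory to a uniform rate.

    Per-coordinate linear interpolation onto a grid from the first to the
    last timestamp. Returns the same trajectory type.
    """
    ts = np.asarray(traj.timestamps, dtype=float)
    if len(ts) < 2:
        raise ContractError("resampling needs at least two samples")
    n_out = int(np.floor((ts[-1] - ts[0]) * rate)) + 1
    grid = ts[0] + np.arange(n_out) / rate

    if isinstance(traj, MarkerTrajectory):
        positions = {
            name: np.column_stack(
                [np.interp(grid, ts, pos[:, j]) for j in range(3)]
            )
            for name, pos in traj.positions.items()
        }
        return MarkerTrajectory(timestamps=grid, positions=positions, source_rate=rate)

    lm = np.asarray(traj.landmarks, dtype=float)
    flat = lm.reshape(len(ts), -1)
    out = np.column_stack([np.interp(grid, ts, flat[:, j]) for j in range(flat.shape[1])])
    return HandTrajectory(
        timestamps=grid,
        landmarks=out.reshape(n_out, lm.shape[1], 3),
        valid=np.ones(n_out, dtype=bool),
        hand_label=traj.hand_label,
    )


def trim_trial(obj, trim_start: float = 2.0, trim_end: float = 1.0):
    """Remove the first ``trim_start`` and last ``trim_end`` seconds.

    Works on any uniform time series in this module (trajectories,
    distance signals). Raises :class:`QualityError` when the input is not
    longer than the combined trim.
    """
    ts = np.asarray(obj.timestamps, dtype=float)
    duration = ts[-1] - ts[0]
    if duration <= trim_start + trim_end:
        raise QualityError(
            f"trial duration {duration:.2f}s too short to trim "
            f"({trim_start}+{trim_end}s)"
        )
    keep = (ts >= ts[0] + trim_start) & (ts <= ts[-1] - trim_end)
    idx = np.flatnonzero(keep)

    if isinstance(obj, DistanceSignal):
        return DistanceSignal(
            timestamps=ts[idx], values=obj.values[idx], rate=obj.rate,
            filtered=obj.filtered,
        )
    if isinstance(obj, MarkerTrajectory):
        return MarkerTrajectory(
            timestamps=ts[idx],
            positions={n: p[idx] for n, p in obj.positions.items()},
            source_rate=obj.source_rate,
        )
    return HandTrajectory(
        timestamps=ts[idx],
        landmarks=obj.landmarks[idx],
        valid=obj.valid[idx],
        interpolated=obj.interpolated[idx],
        hand_label=obj.hand_label,
    )


def thumb_index_distance(traj) -> DistanceSignal:
    """3D Euclidean thumb-tip to index-tip distance in centimeters.

    Hand trajectories are in meters (converted here); reference marker
    trajectories are already centimeters.
    """
    if isinstance(traj, MarkerTrajectory):
        for name in ("thumb_tip", "index_tip"):
            if name not in traj.positions:
                raise ContractError(f"marker trajectory lacks {name!r}")
        thumb = traj.positions["thumb_tip"]
        index = traj.positions["index_tip"]
        scale = 1.0  # already cm
        rate = traj.source_rate
    else:
        thumb = traj.landmarks[:, THUMB_TIP]
        index = traj.landmarks[:, INDEX_TIP]
        scale = 100.0  # m -> cm
        dt = np.diff(traj.timestamps)
        rate = 1.0 / float(np.median(dt)) if len(dt) else float("nan")
    dist = np.linalg.norm(thumb - index, axis=1) * scale
    return DistanceSignal(timestamps=np.asarray(traj.timestamps, dtype=float),
                          values=dist, rate=rate)


def align_by_xcorr(signals: list[DistanceSignal]) -> list[DistanceSignal]:
    """Lag-align 2-3 distance signals by maximizing cross-correlation.

    Signals are mean-centered internally; each non-reference signal (the
    first is the reference) is shifted by the integer lag maximizing its
    cross-correlation with the reference, then all are cut to the common
    overlap. Used only for cross-system comparisons.
    """
    if not 2 <= len(signals) <= 3:
        raise ContractError("alignment expects 2 or 3 signals")
    rates = {round(s.rate, 6) for s in signals}
    if len(rates) != 1:
        raise ContractError("signals must share a sampling rate")
    centered = []
    for s in signals:
        v = s.values - s.values.mean()
        if np.allclose(v, 0.0):
            raise ContractError("zero-variance signal cannot be aligned")
        centered.append(v)

    ref = centered[0]
    lags = [0]
    for v in centered[1:]:
        corr = sps.correlate(v, ref, mode="full")
        lag_axis = sps.correlation_lags(len(v), len(ref), mode="full")
        lags.append(int(lag_axis[np.argmax(corr)]))

    # lag L > 0 means the signal's content starts L samples after the
    # reference's: drop its first L samples (and vice versa via min_lag)
    min_lag = min(lags)
    starts = [lag - min_lag for lag in lags]
    n = min(len(s.values) - start for s, start in zip(signals, starts))
    if n <= 0:
        raise ContractError("no overlap after lag alignment")
    out = []
    for s, start in zip(signals, starts):
        out.append(
            DistanceSignal(
                timestamps=s.timestamps[:n] - s.timestamps[0],
                values=s.values[start : start + n],
                rate=s.rate,
                filtered=s.filtered,
            )
        )
    return out


def lowpass(
    signal: DistanceSignal,
    order: int = 4,
    cutoff_hz: float = 5.0,
    zero_phase: bool = True,
) -> DistanceSignal:
    """Butterworth low-pass the distance signal.

    Zero-phase (forward-backward) by default so cycle timing is not
    lagged; ``zero_phase=False`` selects a single causal pass for parity
    with causal pipelines.
    """
    n = len(signal.values)
    if n <= 3 * (order + 1):
        raise QualityError(f"signal of {n} samples too short for order-{order} filter")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=signal.rate, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, signal.values)
    else:
        filtered = sps.sosfilt(sos, signal.values)
    return DistanceSignal(
        timestamps=signal.timestamps, values=filtered, rate=signal.rate, filtered=True
    )


def velocity(signal: DistanceSignal) -> VelocitySignal:
    """Central-difference velocity of the distance signal (cm/s).

    Interior: ``v[i] = (x[i+1] - x[i-1]) / (2 dt)``; endpoints use
    one-sided differences. Opening (distance increasing) is positive.
    """
    x = signal.values
    if len(x) < 3:
        raise ContractError("velocity needs at least three samples")
    dt = 1.0 / signal.rate
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return VelocitySignal(timestamps=signal.timestamps, values=v)


# ---------------------------------------------------------------------------
# Tap-cycle segmentation and metrics


def segment_tap_cycles(
    signal: DistanceSignal,
    min_prominence_cm: float = 0.5,
    min_separation_s: float = 0.15,
) -> list[tuple[int, int]]:
    """Find tap-cycle boundaries as consecutive distance minima.

    Minima are detected on the negated signal with topographic prominence
    >= ``min_prominence_cm``; the separation constraint is enforced by
    greedy retention in decreasing prominence order. Fewer than two
    minima yields no cycles.
    """
    peaks, props = sps.find_peaks(-signal.values, prominence=min_prominence_cm)
    if len(peaks) == 0:
        return []
    min_sep = min_separation_s * signal.rate
    order = np.argsort(props["prominences"])[::-1]  # highest prominence first
    kept: list[int] = []
    for k in order:
        p = peaks[k]
        if all(abs(p - q) >= min_sep for q in kept):
            kept.append(p)
    minima = sorted(kept)
    return [(minima[i], minima[i + 1]) for i in range(len(minima) - 1)]


def cycle_metrics(
    signal: DistanceSignal,
    vel: VelocitySignal,
    boundaries: list[tuple[int, int]],
) -> list[TapCycle]:
    """Compute per-cycle metrics for each (start, end) minima pair.

    ``Amp`` is the maximum opening within the cycle minus the *initial*
    close position; ``MaxCloseVel`` is reported as a magnitude.
    Degenerate cycles without interior samples are dropped with a warning.
    """
    cycles: list[TapCycle] = []
    for start, end in boundaries:
        if end - start < 2:
            warnings.warn(
                f"dropping degenerate cycle [{start}, {end}] with no interior "
                "samples",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        seg = signal.values[start : end + 1]
        vseg = vel.values[start : end + 1]
        dur = float(signal.timestamps[end] - signal.timestamps[start])
        cycles.append(
            TapCycle(
                start_index=start,
                end_index=end,
                Dur=dur,
                Freq=1.0 / dur,
                Amp=float(seg.max() - seg[0]),
                MaxOpenVel=float(vseg.max()),
                MaxCloseVel=float(abs(vseg.min())),
            )
        )
    return cycles


def _mean_cv(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, float("nan")
    return mean, float(np.std(values, ddof=1) / mean)


def trial_summary(cycles: list[TapCycle], signal: DistanceSignal) -> TrialMetrics:
    """Summarize a trial: tap count, per-cycle means/CVs, and NPL.

    NPL is computed on the whole trimmed, filtered distance signal
    (sum of absolute consecutive differences over total duration),
    independent of cycle detection.
    """
    npl = float(np.sum(np.abs(np.diff(signal.values))) / signal.duration)
    if not cycles:
        nan = float("nan")
        return TrialMetrics(0, nan, nan, nan, nan, nan, nan, nan, nan, npl)
    amp_m, amp_cv = _mean_cv(np.array([c.Amp for c in cycles]))
    freq_m, freq_cv = _mean_cv(np.array([c.Freq for c in cycles]))
    ov_m, ov_cv = _mean_cv(np.array([c.MaxOpenVel for c in cycles]))
    cv_m, cv_cv = _mean_cv(np.array([c.MaxCloseVel for c in cycles]))
    return TrialMetrics(
        TapCount=len(cycles),
        Amp_Mean=amp_m,
        Amp_CV=amp_cv,
        Freq_Mean=freq_m,
        Freq_CV=freq_cv,
        MaxOpenVel_Mean=ov_m,
        MaxOpenVel_CV=ov_cv,
        MaxCloseVel_Mean=cv_m,
        MaxCloseVel_CV=cv_cv,
        NPL=npl,
    )


def trial_metrics_from_trajectory(
    traj, config: PipelineConfig | None = None
) -> TrialMetrics:
    """Run the full fixed-order kinematics pipeline on one trajectory."""
    config = config or PipelineConfig()
    uniform = resample_uniform(traj, rate=config.resample_rate_hz)
    trimmed = trim_trial(uniform, config.trim_start_s, config.trim_end_s)
    dist = thumb_index_distance(trimmed)
    filt = lowpass(
        dist,
        order=config.filter_order,
        cutoff_hz=config.filter_cutoff_hz,
        zero_phase=config.zero_phase,
    )
    vel = velocity(filt)
    boundaries = segment_tap_cycles(
        filt, config.min_prominence_cm, config.min_separation_s
    )
    cycles = cycle_metrics(filt, vel, boundaries)
    return trial_summary(cycles, filt)
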