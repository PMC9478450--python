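"""Reduce a raw measurement cycle to the scalars the velocity methods need.

One measurement cycle consists of a short baseline (~5 s), a heat pulse
(~2 s) and a monitoring phase (~100 s sampled at 0.5 s).  This module turns
the per-channel temperature series of such a cycle into, per radial depth:

* the baseline-subtracted temperature rise series dT(t),
* the HRM log-ratio averaged over the late-time window,
* the downstream peak height and peak time t_m,
* the Peclet number beta = ln(dT_d,max / dT_u,max).

Each radial depth is processed independently, so method selection can differ
between the outer and inner sapwood of the same stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DomainError,
    InsufficientBaselineError,
    LowSignalError,
    UnresolvedPeakError,
)

__all__ = [
    "PulseRecord",
    "PulseSummary",
    "BaselineResult",
    "subtract_baseline",
    "hrm_window_ratio",
    "find_peak",
    "peclet_beta",
    "summarize_pulse",
    "QC_UNSTABLE_BASELINE",
    "QC_INCOMPLETE",
    "QC_DMA_FALLBACK",
    "QC_NEGATIVE_PEAK",
]

# QC flag vocabulary (serialized into the results CSV as ;-joined strings)
QC_UNSTABLE_BASELINE = "unstable-baseline"
QC_INCOMPLETE = "incomplete"
QC_DMA_FALLBACK = "dma-fallback"
QC_NEGATIVE_PEAK = "negative-peak"

DEFAULT_DT_FLOOR = 0.001  # K; below this a log-ratio sample is noise
DEFAULT_BASELINE_SD_QC = 0.05  # K
DEFAULT_SMOOTH_WINDOW = 3  # samples


@dataclass
class PulseRecord:
    """One measurement cycle.

    timestamps are seconds since the start of the heat pulse; baseline
    samples carry negative timestamps.  ``channels`` maps a channel name to
    its temperature series (degC), ``channel_map`` maps the same name to a
    (side, radial depth cm) pair with side in {"down", "up"}.
    """

    cycle_id: str
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    t0: float
    channel_map: dict[str, tuple[str, float]]
    start_time: str | None = None  # ISO 8601 of pulse start, if known
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise DomainError(f"cycle {self.cycle_id}: timestamps not increasing")
        for name, series in self.channels.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.timestamps.shape:
                raise DomainError(
                    f"cycle {self.cycle_id}: channel {name} length mismatch"
                )
            self.channels[name] = arr

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.timestamps < 0.0

    @property
    def depths(self) -> list[float]:
        return sorted({d for _, d in self.channel_map.values()})

    def channel_at(self, side: str, depth: float) -> str:
        for name, (s, d) in self.channel_map.items():
            if s == side and np.isclose(d, depth):
                return name
        raise KeyError(f"no {side} channel at depth {depth} cm")


@dataclass
class BaselineResult:
    """Baseline-subtracted series plus the QC statistics behind them."""

    delta: dict[str, np.ndarray]  # per channel, aligned with record.timestamps
    baseline_mean: dict[str, float]
    baseline_sd: dict[str, float]
    qc_flags: set[str]


@dataclass
class PulseSummary:
    """Per-depth scalar summary of one cycle."""

    depth: float
    dT_d_max: float
    dT_u_max: float
    t_m_down: float | None  # None if the downstream peak was unresolved
    ln_ratio_window: float | None  # None if the window had no usable samples
    beta: float | None
    n_window_excluded: int = 0
    qc_flags: set[str] = field(default_factory=set)


def subtract_baseline(
    record: PulseRecord, sd_threshold: float = DEFAULT_BASELINE_SD_QC
) -> BaselineResult:
    """Per channel: dT(t) = T(t) - mean(baseline samples).

    Requires at least 3 baseline samples.  A baseline standard deviation
    above ``sd_threshold`` flags the record "unstable-baseline" but does not
    stop processing.
    """
    mask = record.baseline_mask
    n_base = int(mask.sum())
    if n_base < 3:
        raise InsufficientBaselineError(
            f"cycle {record.cycle_id}: {n_base} baseline samples (< 3)"
        )
    delta, means, sds = {}, {}, {}
    flags: set[str] = set()
    for name, series in record.channels.items():
        mean = float(np.mean(series[mask]))
        sd = float(np.std(series[mask], ddof=0))
        delta[name] = series - mean
        means[name], sds[name] = mean, sd
        if sd > sd_threshold:
            flags.add(QC_UNSTABLE_BASELINE)
    return BaselineResult(delta, means, sds, flags)


def hrm_window_ratio(
    t: np.ndarray,
    dT_d: np.ndarray,
    dT_u: np.ndarray,
    window: tuple[float, float] = (60.0, 100.0),
    floor: float = DEFAULT_DT_FLOOR,
) -> tuple[float, int]:
    """Mean of ln(dT_d/dT_u) over window samples; returns (ratio, n_excluded).

    The log-ratio is computed per sample and then averaged.  Samples where
    either rise is at or below ``floor`` are excluded (and counted); if every
    window sample is excluded the heat pulse did not reach the sensors and a
    :class:`LowSignalError` is raised.
    """
    t = np.asarray(t, float)
    in_win = (t >= window[0]) & (t <= window[1])
    if not np.any(in_win):
        raise LowSignalError(f"no samples inside window {window}")
    d = np.asarray(dT_d, float)[in_win]
    u = np.asarray(dT_u, float)[in_win]
    usable = (d > floor) & (u > floor)
    n_excluded = int((~usable).sum())
    if not np.any(usable):
        raise LowSignalError(
            f"all {len(d)} window samples below the {floor} K floor"
        )
    return float(np.mean(np.log(d[usable] / u[usable]))), n_excluded


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinking (window must be odd)."""
    if window <= 1:
        return y
    if window % 2 == 0:
        raise DomainError(f"smoothing window must be odd, got {window}")
    kernel = np.ones(window) / window
    # reflect-pad so edges average over a shrunk but centered neighbourhood
    half = window // 2
    padded = np.concatenate([y[half:0:-1], y, y[-2 : -2 - half : -1]])
    return np.convolve(padded, kernel, mode="valid")


def find_peak(
    t: np.ndarray,
    dT: np.ndarray,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    interpolate: bool = True,
) -> tuple[float, float]:
    """Locate the temperature-rise maximum: returns (dT_max, t_m).

    A short moving average suppresses quantisation/noise, the discrete argmax
    is then refined by a parabola through the peak sample and its two
    neighbours.  A peak on the final sample means the monitoring window was
    too short to resolve it.
    """
    t = np.asarray(t, float)
    y = np.asarray(dT, float)
    if len(y) < 5:
        raise DomainError(f"need >= 5 post-pulse samples, got {len(y)}")
    ys = _moving_average(y, smooth_window)
    i = int(np.argmax(ys))
    if i == len(ys) - 1:
        raise UnresolvedPeakError(
            "maximum on the last sample: monitoring window too short"
        )
    if not interpolate or i == 0:
        return float(ys[i]), float(t[i])
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:  # flat-topped: keep the discrete sample
        return float(y1), float(t[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    dt = t[i + 1] - t[i] if shift >= 0 else t[i] - t[i - 1]
    peak = y1 - 0.25 * (y0 - y2) * shift
    return float(peak), float(t[i] + shift * dt)


def peclet_beta(
    dT_d_max: float, dT_u_max: float, floor: float = DEFAULT_DT_FLOOR
) -> float:
    """Peclet number beta = ln(dT_d,max / dT_u,max)."""
    if dT_u_max <= floor:
        raise LowSignalError(
            f"upstream maximum {dT_u_max!r} K at or below the {floor} K floor"
        )
    if dT_d_max <= 0.0:
        raise LowSignalError(f"non-positive downstream maximum {dT_d_max!r} K")
    return float(np.log(dT_d_max / dT_u_max))


def summarize_pulse(
    record: PulseRecord,
    window: tuple[float, float] = (60.0, 100.0),
    floor: float = DEFAULT_DT_FLOOR,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_sd_threshold: float = DEFAULT_BASELINE_SD_QC,
) -> list[PulseSummary]:
    """Full per-depth reduction of one cycle.

    beta is computed from the same smoothed maxima as ``find_peak`` so the
    HRM/Tmax selection is robust to single-sample noise.  Failures that are
    per-depth (unresolved peak, low upstream signal) are recorded in the
    summary rather than raised, so one bad depth never sinks the cycle.
    """
    base = subtract_baseline(record, sd_threshold=baseline_sd_threshold)
    post = record.timestamps > 0.0
    t_post = record.timestamps[post]
    out: list[PulseSummary] = []
    for depth in record.depths:
        flags = set(base.qc_flags) | set(record.qc_flags)
        ch_d = record.channel_at("down", depth)
        ch_u = record.channel_at("up", depth)
        dT_d = base.delta[ch_d][post]
        dT_u = base.delta[ch_u][post]

        t_m: float | None
        try:
            dmax, t_m = find_peak(t_post, dT_d, smooth_window=smooth_window)
        except UnresolvedPeakError:
            smoothed = _moving_average(dT_d, smooth_window)
            dmax, t_m = float(np.max(smoothed)), None
            flags.add("unresolved-peak")
        umax = float(np.max(_moving_average(dT_u, smooth_window)))
        if dmax < 0.0 or umax < 0.0:
            flags.add(QC_NEGATIVE_PEAK)

        ln_ratio: float | None
        n_excl = 0
        try:
            ln_ratio, n_excl = hrm_window_ratio(
                t_post, dT_d, dT_u, window=window, floor=floor
            )
        except LowSignalError:
            ln_ratio = None
            flags.add("low-signal-window")

        try:
            beta = peclet_beta(dmax, umax, floor=floor)
        except LowSignalError:
            beta = None
            flags.add("low-upstream-signal")

        out.append(
            PulseSummary(
                depth=depth,
                dT_d_max=dmax,
                dT_u_max=umax,
                t_m_down=t_m,
                ln_ratio_window=ln_ratio,
                beta=beta,
                n_window_excluded=n_excl,
                qc_flags=flags,
            )
        )
    return out
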