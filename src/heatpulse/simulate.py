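"""Forward model of heat-pulse temperature traces.

The sapwood is idealised as a homogeneous, infinite medium with thermal
diffusivity k through which sap moves the heat field at a uniform heat-pulse
velocity v.  An ideal line heater at x = 0 fired instantaneously produces,
at signed axial offset x (positive toward the downstream probe),

    dT(x, t) = q / (4 pi k t) * exp(-(x - v t)^2 / (4 k t)),

the classical conduction-convection line-source solution.  A real pulse of
duration t0 is the uniform superposition of instantaneous sources over
[0, min(t, t0)], evaluated here by adaptive quadrature.

This module doubles as the package's synthetic-data generator: it emits
complete measurement cycles (baseline / pulse / monitor phases on a 0.5 s
grid by default) with Gaussian sensor noise and ADC-style quantisation, and
is the correctness oracle behind the estimator tests: on the ideal medium
the HRM log-ratio identity and the Tmax peak-time quadratic hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .errors import DomainError
from .processing import PulseRecord
from .velocity import CM_S_TO_CM_HR, ProbeGeometry

__all__ = [
    "MediumParams",
    "NoiseModel",
    "CycleTiming",
    "instantaneous_pulse_dT",
    "finite_pulse_dT",
    "generate_pulse_record",
    "generate_cycles",
    "peak_time",
]

QUAD_RTOL = 1e-8


@dataclass(frozen=True)
class MediumParams:
    """Physical truth of a simulated stem.

    v_h is the true heat-pulse velocity in cm hr^-1 (positive = up-tree,
    toward the downstream probe; reverse flow is allowed).  q_amp scales the
    instantaneous-pulse response (K cm^2); the default gives a ~1.5 K
    downstream peak at zero flow with the default geometry.  t0 is the heat
    pulse duration in seconds.
    """

    k: float = 2.5e-3  # cm^2 s^-1
    v_h: float = 0.0  # cm hr^-1
    q_amp: float = 3.2  # K cm^2
    t0: float = 2.0  # s

    def __post_init__(self):
        if self.k <= 0:
            raise DomainError("thermal diffusivity k must be > 0")
        if self.t0 < 0:
            raise DomainError("pulse duration t0 must be >= 0")

    @property
    def v_cm_s(self) -> float:
        return self.v_h / CM_S_TO_CM_HR


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise and ADC quantisation applied to simulated traces.

    sigma is i.i.d. Gaussian temperature noise (K); quant_step rounds the
    recorded temperature to the nearest multiple (0.005 K approximates a
    16-bit ADC reading a 10k NTC divider; 0 disables).  The same seed always
    reproduces the same trace.
    """

    sigma: float = 0.01  # K
    quant_step: float = 0.005  # K
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.quant_step < 0:
            raise DomainError("sigma and quant_step must be >= 0")


#: Noise model with both noise and quantisation disabled.
NOISELESS = NoiseModel(sigma=0.0, quant_step=0.0, seed=0)


@dataclass(frozen=True)
class CycleTiming:
    """Measurement-cycle program: 5 s baseline, pulse, 100 s monitoring."""

    baseline_duration: float = 5.0  # s
    monitor_duration: float = 100.0  # s
    sample_interval: float = 0.5  # s
    ambient: float = 20.0  # degC
    drift_rate: float = 0.0  # K s^-1, optional linear baseline drift

    def __post_init__(self):
        if self.sample_interval <= 0:
            raise DomainError("sample_interval must be > 0")
        if self.baseline_duration < 3 * self.sample_interval:
            raise DomainError("baseline must cover at least 3 samples")

    def grid(self) -> np.ndarray:
        """Sample times relative to the pulse start (baseline negative)."""
        dt = self.sample_interval
        n_base = int(round(self.baseline_duration / dt))
        n_post = int(round(self.monitor_duration / dt))
        base = -dt * np.arange(n_base, 0, -1)
        post = dt * np.arange(1, n_post + 1)
        return np.concatenate([base, post])


def instantaneous_pulse_dT(x, t, medium: MediumParams):
    """Temperature rise (K) from an instantaneous line pulse at offset x, time t.

    Vectorised over x and t (broadcasting); every time must be > 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0.0):
        raise DomainError("time since pulse must be > 0")
    x_arr = np.asarray(x, dtype=float)
    v = medium.v_cm_s
    out = (
        medium.q_amp
        / (4.0 * math.pi * medium.k * t_arr)
        * np.exp(-((x_arr - v * t_arr) ** 2) / (4.0 * medium.k * t_arr))
    )
    return float(out) if out.ndim == 0 else out


def _finite_pulse_scalar(x: float, t: float, medium: MediumParams) -> float:
    t0 = medium.t0
    upper = min(t, t0)
    # age of the oldest contributing source element is t, youngest t - upper
    val, err = quad(
        lambda s: instantaneous_pulse_dT(x, t - s, medium),
        0.0,
        upper * (1.0 - 1e-12) if upper == t else upper,
        epsrel=QUAD_RTOL,
        epsabs=1e-13,
        limit=200,
    )
    if not np.isfinite(val):
        raise DomainError(
            f"quadrature failed at x={x}, t={t}: value={val}, err={err}"
        )
    return val / t0


def finite_pulse_dT(x, t, medium: MediumParams):
    """Temperature rise (K) for a top-hat heat pulse of duration medium.t0.

    Uniform superposition of instantaneous solutions over [0, min(t, t0)],
    by adaptive quadrature (relative tolerance 1e-8).  Reduces to the
    instantaneous solution when t0 = 0.  Vectorised over t.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0.0):
        raise DomainError("time since pulse must be > 0")
    if medium.t0 == 0.0:
        return instantaneous_pulse_dT(x, t, medium)
    out = np.array([_finite_pulse_scalar(x, ti, medium) for ti in t_arr])
    return float(out[0]) if np.isscalar(t) else out


def peak_time(medium: MediumParams, x: float) -> float:
    """True downstream peak time for the simulated medium (closed form).

    Instantaneous pulse: the positive root of v^2 t^2 + 4 k t - x^2 = 0.
    Finite pulse: the root of f(t) = f(t - t0) with f the instantaneous
    kernel, bracketed and bisected (the peak condition for a top-hat pulse).
    """
    v, k, t0 = abs(medium.v_cm_s), medium.k, medium.t0
    if v == 0.0:
        t_inst = x * x / (4.0 * k)
    else:
        t_inst = (-4.0 * k + math.sqrt(16.0 * k * k + 4.0 * v * v * x * x)) / (
            2.0 * v * v
        )
    if t0 == 0.0:
        return t_inst

    def g(t):
        return instantaneous_pulse_dT(x, t, medium) - instantaneous_pulse_dT(
            x, t - t0, medium
        )

    from scipy.optimize import brentq

    lo = t_inst + 1e-9  # peak of the finite pulse lags the instantaneous one
    hi = t_inst + t0
    while g(hi) > 0:
        hi += t0
    return float(brentq(g, lo, hi, xtol=1e-10))


def generate_pulse_record(
    geometry: ProbeGeometry,
    medium: MediumParams,
    noise: NoiseModel = NOISELESS,
    timing: CycleTiming = CycleTiming(),
    cycle_id: str = "0",
) -> PulseRecord:
    """Simulate one complete measurement cycle.

    Channels ch1..chN are the downstream sensors (shallow to deep) followed
    by the upstream ones.  The medium is radially homogeneous, so all depths
    on a side see the same physics; depth structure enters through geometry
    and the annulus weighting downstream of the estimators.  Baseline
    samples carry ambient (plus optional drift) and noise only.
    """
    t_grid = timing.grid()
    post = t_grid > 0.0
    n_depths = len(geometry.depths)

    ambient = timing.ambient + timing.drift_rate * (t_grid - t_grid[0])
    dT_down = np.zeros_like(t_grid)
    dT_up = np.zeros_like(t_grid)
    dT_down[post] = finite_pulse_dT(geometry.x_d, t_grid[post], medium)
    dT_up[post] = finite_pulse_dT(-geometry.x_u, t_grid[post], medium)

    rng = np.random.default_rng(noise.seed)
    channels: dict[str, np.ndarray] = {}
    channel_map: dict[str, tuple[str, float]] = {}
    for i, (side, clean) in enumerate(
        [("down", dT_down)] * n_depths + [("up", dT_up)] * n_depths
    ):
        depth = geometry.depths[i % n_depths]
        name = f"ch{i + 1}"
        series = ambient + clean
        if noise.sigma > 0:
            series = series + rng.normal(0.0, noise.sigma, size=series.shape)
        if noise.quant_step > 0:
            series = np.round(series / noise.quant_step) * noise.quant_step
        channels[name] = series
        channel_map[name] = (side, depth)

    return PulseRecord(
        cycle_id=str(cycle_id),
        timestamps=t_grid,
        channels=channels,
        t0=medium.t0,
        channel_map=channel_map,
    )


def generate_cycles(
    n_cycles: int,
    geometry: ProbeGeometry,
    medium: MediumParams,
    noise: NoiseModel = NOISELESS,
    timing: CycleTiming = CycleTiming(),
) -> list[PulseRecord]:
    """Simulate a sequence of cycles with per-cycle derived noise seeds."""
    records = []
    for i in range(n_cycles):
        cyc_noise = NoiseModel(
            sigma=noise.sigma,
            quant_step=noise.quant_step,
            seed=(noise.seed * 100_003 + i) % (2**31 - 1),
        )
        records.append(
            generate_pulse_record(
                geometry, medium, cyc_noise, timing, cycle_id=str(i)
            )
        )
    return records
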