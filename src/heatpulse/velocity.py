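"""Heat-pulse velocity estimators: HRM, Tmax and the Dual Method Approach.

All estimators work internally in cm s^-1 and report in cm hr^-1 (the
field's convention).  The Heat Ratio Method resolves low and reverse flows
from the log-ratio of the up-/downstream temperature rises; the Tmax method
resolves mid/high flows from the downstream peak time; the Dual Method
Approach (DMA) picks between them per measurement using the Peclet number
beta = ln(dT_d,max / dT_u,max), with beta <= 1 selecting HRM.

The finite-pulse Tmax form implemented here is exact for a line source
heated uniformly over [0, t0]: the peak condition equates the instantaneous
kernel at t_m and t_m - t0, which solves to

    V = sqrt( (4k/t0) ln(1 - t0/t_m) + x_d^2 / (t_m (t_m - t0)) ).

It reduces to the instantaneous form sqrt(x_d^2 - 4k t_m)/t_m as t0 -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BelowTmaxResolutionError, DomainError, NoEstimateError
from .processing import QC_DMA_FALLBACK, PulseSummary

__all__ = [
    "ProbeGeometry",
    "VelocityEstimate",
    "annuli_from_depths",
    "hrm_velocity",
    "hrm_velocity_asym",
    "tmax_velocity",
    "tmax_velocity_corrected",
    "dma_select",
    "estimate_k_zero_flow",
    "BETA_THRESHOLD",
    "CM_S_TO_CM_HR",
]

CM_S_TO_CM_HR = 3600.0

# The DMA switch point. Deliberately not configurable: moving it silently
# changes which estimator produced a number.
BETA_THRESHOLD = 1.0


def annuli_from_depths(
    depths, sapwood_radius: float, heartwood_radius: float = 0.0
) -> list[tuple[float, float]]:
    """Assign a sapwood annulus (r_inner, r_outer) to each sensor depth.

    Depths are measured inward from the cambium, radii from the stem centre.
    Boundaries between neighbouring sensors sit at the midpoint of their
    depths; the shallowest sensor extends out to the sapwood radius and the
    deepest inward to the heartwood boundary.  Returned in the same order as
    ``depths`` (which must be sorted shallow to deep).
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise DomainError("depths must be strictly increasing (shallow to deep)")
    if sapwood_radius <= heartwood_radius:
        raise DomainError("sapwood_radius must exceed heartwood_radius")
    bounds_in = []  # depth of each annulus boundary, outermost first
    for a, b in zip(depths, depths[1:]):
        bounds_in.append(0.5 * (a + b))
    outer_depths = [0.0] + bounds_in
    inner_depths = bounds_in + [sapwood_radius - heartwood_radius]
    annuli = []
    for d_out, d_in in zip(outer_depths, inner_depths):
        r_out = sapwood_radius - d_out
        r_in = sapwood_radius - d_in
        if r_in < heartwood_radius - 1e-12 or r_in >= r_out:
            raise DomainError(
                f"invalid annulus ({r_in}, {r_out}) for sapwood radius "
                f"{sapwood_radius}: sensor depths exceed the sapwood band"
            )
        annuli.append((r_in, r_out))
    return annuli


@dataclass(frozen=True)
class ProbeGeometry:
    """Axial heater-to-sensor spacings and radial sensor layout.

    x_d / x_u: distance (cm) from the heater probe to the downstream /
    upstream temperature probe.  depths: radial sensor positions (cm from
    cambium, shallow to deep).  annuli: the sapwood ring assigned to each
    depth for whole-tree integration; computed from the depths and sapwood
    band if not given explicitly.
    """

    x_d: float = 0.5
    x_u: float = 0.5
    depths: tuple[float, ...] = (0.5, 1.5, 2.5)
    annuli: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.x_d <= 0 or self.x_u <= 0:
            raise DomainError("probe spacings x_d, x_u must be > 0")
        if self.annuli is not None:
            if len(self.annuli) != len(self.depths):
                raise DomainError("need one annulus per sensor depth")
            for r_in, r_out in self.annuli:
                if not r_in < r_out:
                    raise DomainError(f"annulus ({r_in}, {r_out}): r_in >= r_out")

    def with_annuli(self, sapwood_radius: float, heartwood_radius: float = 0.0):
        return ProbeGeometry(
            x_d=self.x_d,
            x_u=self.x_u,
            depths=self.depths,
            annuli=tuple(
                annuli_from_depths(self.depths, sapwood_radius, heartwood_radius)
            ),
        )


@dataclass
class VelocityEstimate:
    """Outcome of the DMA for one depth of one cycle."""

    depth: float
    beta: float
    v_hrm: float | None  # cm hr^-1, None if the method failed
    v_tmax: float | None
    method_selected: str  # "HRM" | "Tmax"
    v_h: float  # cm hr^-1, the selected estimate
    failures: dict[str, str] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)


def hrm_velocity(ln_ratio: float, k: float, x: float) -> float:
    """Symmetric-probe HRM: V = (k/x) ln(dT_d/dT_u), reported in cm hr^-1."""
    if k <= 0 or x <= 0:
        raise DomainError("k and x must be > 0")
    return (k / x) * ln_ratio * CM_S_TO_CM_HR


def hrm_velocity_asym(
    ln_ratio: float, k: float, x_d: float, x_u: float, t: float, t0: float = 0.0
) -> float:
    """HRM generalised to unequal spacings and a finite pulse.

    V = 2k ln(dT_d/dT_u)/(x_d + x_u) + (x_d - x_u)/(2 (t - t0/2)), cm hr^-1,
    where t is the representative measurement time (the HRM-window midpoint
    by default in the pipeline).  Identical to ``hrm_velocity`` when
    x_d == x_u.
    """
    if k <= 0 or x_d <= 0 or x_u <= 0:
        raise DomainError("k, x_d, x_u must be > 0")
    if t <= t0 / 2.0:
        raise DomainError(f"measurement time t={t} must exceed t0/2={t0 / 2}")
    v = 2.0 * k * ln_ratio / (x_d + x_u) + (x_d - x_u) / (2.0 * (t - t0 / 2.0))
    return v * CM_S_TO_CM_HR


def tmax_velocity(t_m: float, k: float, x_d: float) -> float:
    """Instantaneous-pulse Tmax: V = sqrt(x_d^2 - 4 k t_m)/t_m, cm hr^-1."""
    if t_m <= 0:
        raise DomainError(f"peak time must be > 0, got {t_m}")
    if k <= 0 or x_d <= 0:
        raise DomainError("k and x_d must be > 0")
    radicand = x_d * x_d - 4.0 * k * t_m
    if radicand < 0:
        raise BelowTmaxResolutionError(
            f"x_d^2 = {x_d * x_d:.4g} <= 4 k t_m = {4 * k * t_m:.4g}: "
            "flow too slow for Tmax (conduction-dominated)"
        )
    return math.sqrt(radicand) / t_m * CM_S_TO_CM_HR


def tmax_velocity_corrected(t_m: float, k: float, x_d: float, t0: float) -> float:
    """Finite-pulse Tmax (exact for a top-hat pulse of duration t0), cm hr^-1."""
    if t0 <= 0:
        raise DomainError(f"pulse duration must be > 0, got {t0}")
    if t_m <= t0:
        raise DomainError(f"peak time {t_m} s must exceed pulse duration {t0} s")
    if k <= 0 or x_d <= 0:
        raise DomainError("k and x_d must be > 0")
    radicand = (4.0 * k / t0) * math.log1p(-t0 / t_m) + x_d * x_d / (
        t_m * (t_m - t0)
    )
    if radicand < 0:
        raise BelowTmaxResolutionError(
            "negative radicand: flow too slow for the finite-pulse Tmax"
        )
    return math.sqrt(radicand) * CM_S_TO_CM_HR


def estimate_k_zero_flow(
    record,
    geometry: ProbeGeometry,
    fit_window: tuple[float, float] = (20.0, 100.0),
    floor: float = 0.001,
) -> float:
    """Estimate thermal diffusivity from a known zero-flow cycle. Experimental.

    At v = 0 the downstream rise follows ln(dT) + ln(t) = const - x_d^2/(4k t),
    so a linear fit of ln(dT t) against 1/t over the late-time window yields
    k from the slope.  Finite pulse duration is absorbed by shifting times to
    the pulse midpoint.  Only valid if sap flow really was zero (e.g. a
    pre-dawn cut-stem check); any advection biases k upward.
    """
    from .processing import subtract_baseline  # local import to avoid cycle

    base = subtract_baseline(record)
    post = record.timestamps > 0.0
    t = record.timestamps[post] - record.t0 / 2.0
    ch_d = record.channel_at("down", record.depths[0])
    dT = base.delta[ch_d][post]
    sel = (t >= fit_window[0]) & (t <= fit_window[1]) & (dT > floor)
    if sel.sum() < 5:
        raise DomainError("too few usable samples in the diffusivity fit window")
    slope, _ = np.polyfit(1.0 / t[sel], np.log(dT[sel] * t[sel]), 1)
    if slope >= 0:
        raise DomainError(
            "non-negative decay slope: trace inconsistent with zero-flow cooling"
        )
    return float(-geometry.x_d**2 / (4.0 * slope))


def dma_select(
    summary: PulseSummary,
    geometry: ProbeGeometry,
    k: float,
    t0: float,
    hrm_window: tuple[float, float] = (60.0, 100.0),
) -> VelocityEstimate:
    """Apply the DMA rule to one per-depth summary.

    Computes both estimators where their domains allow, then selects HRM if
    beta <= 1 and Tmax otherwise.  If the selected method failed, the other
    is used and the estimate flagged "dma-fallback"; if both failed a
    :class:`NoEstimateError` is raised.
    """
    failures: dict[str, str] = {}
    flags = set(summary.qc_flags)

    v_hrm: float | None = None
    if summary.ln_ratio_window is None:
        failures["HRM"] = "no usable samples in the HRM window"
    else:
        t_rep = 0.5 * (hrm_window[0] + hrm_window[1])
        try:
            v_hrm = hrm_velocity_asym(
                summary.ln_ratio_window, k, geometry.x_d, geometry.x_u, t_rep, t0
            )
        except DomainError as exc:
            failures["HRM"] = str(exc)

    v_tmax: float | None = None
    if summary.t_m_down is None:
        failures["Tmax"] = "downstream peak unresolved"
    else:
        try:
            if t0 > 0:
                v_tmax = tmax_velocity_corrected(summary.t_m_down, k, geometry.x_d, t0)
            else:
                v_tmax = tmax_velocity(summary.t_m_down, k, geometry.x_d)
        except (BelowTmaxResolutionError, DomainError) as exc:
            failures["Tmax"] = str(exc)

    if summary.beta is None:
        # no upstream signal: only Tmax can stand on its own
        beta = math.inf
    else:
        beta = summary.beta
    preferred = "HRM" if beta <= BETA_THRESHOLD else "Tmax"
    other = "Tmax" if preferred == "HRM" else "HRM"
    by_name = {"HRM": v_hrm, "Tmax": v_tmax}

    if by_name[preferred] is not None:
        selected = preferred
    elif by_name[other] is not None:
        selected = other
        flags.add(QC_DMA_FALLBACK)
    else:
        raise NoEstimateError(
            f"depth {summary.depth} cm: both methods failed ({failures})"
        )

    return VelocityEstimate(
        depth=summary.depth,
        beta=beta,
        v_hrm=v_hrm,
        v_tmax=v_tmax,
        method_selected=selected,
        v_h=float(by_name[selected]),
        failures=failures,
        qc_flags=flags,
    )
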