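"""From corrected heat-pulse velocity to sap flux density and whole-tree flow.

Probe installation wounds the xylem; the empirical multiplicative wound
correction V_c = B * V_h compensates.  Corrected velocity converts to sap
flux density through the heat capacity balance of the sapwood matrix,

    SFD = (rho_b / rho_s) (m_c + c_dw / c_s) V_c      [g cm^-2 s^-1],

and per-depth SFD integrates to whole-tree flow by weighting each sensor's
annulus of conducting sapwood:  F = sum_j pi (r_j^2 - r_{j-1}^2) SFD_j.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import DomainError
from .velocity import CM_S_TO_CM_HR, ProbeGeometry, VelocityEstimate

__all__ = [
    "WoodProperties",
    "SapFlowResult",
    "wound_correct",
    "sap_flux_density",
    "sfd_multiplier",
    "whole_tree_flow",
    "compute_sap_flow",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WoodProperties:
    """Sapwood physical properties needed by the velocity-to-flux conversion.

    rho_b: dry wood density (g cm^-3); m_c: moisture content (g water per g
    dry wood); c_dw: specific heat of dry wood (J g^-1 K^-1); c_s / rho_s:
    specific heat and density of sap, defaulting to water.  wound_B is the
    dimensionless wound-correction coefficient; the default of 1.0 applies
    no correction and should be replaced with the value for the actual drill
    and probe diameters from published wound-coefficient tables.
    """

    rho_b: float
    m_c: float
    c_dw: float
    c_s: float = 4.186
    rho_s: float = 1.0
    wound_B: float = 1.0

    def __post_init__(self):
        for name in ("rho_b", "m_c", "c_dw", "c_s", "rho_s", "wound_B"):
            if getattr(self, name) <= 0:
                raise DomainError(f"WoodProperties.{name} must be > 0")
        if self.wound_B < 1.0:
            log.warning(
                "wound coefficient B = %.3g < 1: wound corrections normally "
                "increase velocity; check the value",
                self.wound_B,
            )
        if self.wound_B == 1.0:
            log.warning(
                "wound coefficient B = 1.0: no wound correction applied; "
                "supply the coefficient for your drill/probe diameters for "
                "quantitative work"
            )


@dataclass
class SapFlowResult:
    """Per-depth corrected velocity and SFD plus the whole-tree total."""

    depths: list[float]
    v_c: list[float]  # cm hr^-1
    sfd: list[float]  # g cm^-2 s^-1
    annulus_areas: list[float]  # cm^2
    F: float  # g s^-1


def wound_correct(v_h: float, B: float) -> float:
    """V_c = B * V_h (cm hr^-1); sign-preserving, so reverse flow stays negative."""
    if B <= 0:
        raise DomainError(f"wound coefficient B must be > 0, got {B}")
    return B * v_h


def sfd_multiplier(wood: WoodProperties) -> float:
    """The dimensionless factor (rho_b/rho_s)(m_c + c_dw/c_s)."""
    return (wood.rho_b / wood.rho_s) * (wood.m_c + wood.c_dw / wood.c_s)


def sap_flux_density(v_c: float, wood: WoodProperties) -> float:
    """Sap flux density (g cm^-2 s^-1) from corrected velocity (cm hr^-1)."""
    return sfd_multiplier(wood) * (v_c / CM_S_TO_CM_HR)


def whole_tree_flow(
    sfd_by_depth, annuli, missing: str = "error"
) -> tuple[float, list[float]]:
    """Annulus-weighted whole-tree flow: returns (F in g s^-1, areas in cm^2).

    ``sfd_by_depth`` may contain None for depths that produced no estimate;
    the ``missing`` policy is "error" (default) or "drop" (ignore that
    annulus, effectively treating its flow as unmeasured).
    """
    sfd_by_depth = list(sfd_by_depth)
    annuli = list(annuli)
    if len(sfd_by_depth) != len(annuli):
        raise DomainError(
            f"{len(sfd_by_depth)} SFD values for {len(annuli)} annuli"
        )
    if missing not in ("error", "drop"):
        raise DomainError(f"unknown missing policy {missing!r}")
    total = 0.0
    areas = []
    for sfd, (r_in, r_out) in zip(sfd_by_depth, annuli):
        if not r_in < r_out:
            raise DomainError(f"annulus ({r_in}, {r_out}): r_in >= r_out")
        area = math.pi * (r_out * r_out - r_in * r_in)
        areas.append(area)
        if sfd is None:
            if missing == "error":
                raise DomainError(
                    f"no SFD for annulus ({r_in}, {r_out}) and policy is 'error'"
                )
            continue
        total += area * sfd
    return total, areas


def compute_sap_flow(
    estimates: list[VelocityEstimate],
    geometry: ProbeGeometry,
    wood: WoodProperties,
    missing: str = "error",
) -> SapFlowResult:
    """Wound-correct, convert and integrate one cycle's velocity estimates."""
    if geometry.annuli is None:
        raise DomainError(
            "geometry has no annuli; call ProbeGeometry.with_annuli or supply them"
        )
    by_depth = {e.depth: e for e in estimates}
    v_c, sfd = [], []
    for depth in geometry.depths:
        est = by_depth.get(depth)
        if est is None:
            v_c.append(None)
            sfd.append(None)
        else:
            vc = wound_correct(est.v_h, wood.wound_B)
            v_c.append(vc)
            sfd.append(sap_flux_density(vc, wood))
    F, areas = whole_tree_flow(sfd, geometry.annuli, missing=missing)
    return SapFlowResult(
        depths=list(geometry.depths),
        v_c=v_c,
        sfd=sfd,
        annulus_areas=areas,
        F=F,
    )
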