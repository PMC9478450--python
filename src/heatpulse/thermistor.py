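"""NTC thermistor conversion: divider voltage -> resistance -> temperature.

The logger excites a 10 kOhm NTC thermistor through a fixed resistor from a
precision voltage reference and digitises the divider voltage.  Conversion to
temperature uses the Steinhart-Hart equation

    1/T = A + B ln(R) + C ln(R)^3        (T in kelvin, R in ohm)

Coefficients shipped as defaults are fitted to a generic curve-type 10 kOhm
NTC resistance table (32650 / 10000 / 3603 ohm at 0 / 25 / 50 degC); any
calibrated deployment should override them with coefficients fitted to the
actual part.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, OutOfRangeError

__all__ = [
    "DividerTopology",
    "ThermistorCal",
    "fit_steinhart_hart",
    "adc_to_resistance",
    "resistance_to_temperature",
    "temperature_to_resistance",
    "voltage_to_temperature",
    "temperature_to_voltage",
    "GENERIC_10K_RT_TRIPLE",
]

# (degC, ohm) triple for a generic 10k NTC, used to fit the default coefficients
GENERIC_10K_RT_TRIPLE = ((0.0, 32650.0), (25.0, 10000.0), (50.0, 3603.0))

_ZERO_C = 273.15


class DividerTopology(str, enum.Enum):
    """Where the thermistor sits in the divider and what is read.

    THERMISTOR_BOTTOM: thermistor between the ADC node and ground, fixed
    resistor to v_ref; the ADC reads the voltage across the thermistor
    (the default, matching the reference circuit).
    THERMISTOR_TOP: thermistor to v_ref, fixed resistor to ground; the ADC
    reads the voltage across the fixed resistor.
    """

    THERMISTOR_BOTTOM = "thermistor_bottom"
    THERMISTOR_TOP = "thermistor_top"


def fit_steinhart_hart(points) -> tuple[float, float, float]:
    """Fit (A, B, C) through three (temperature degC, resistance ohm) points.

    Exact 3x3 linear solve in the variables (1, ln R, ln^3 R); the fitted
    coefficients reproduce the three anchors to machine precision.
    """
    pts = list(points)
    if len(pts) != 3:
        raise DomainError(f"Steinhart-Hart fit needs exactly 3 points, got {len(pts)}")
    design = np.array([[1.0, math.log(r), math.log(r) ** 3] for _, r in pts])
    rhs = np.array([1.0 / (t + _ZERO_C) for t, _ in pts])
    a, b, c = np.linalg.solve(design, rhs)
    return float(a), float(b), float(c)


_DEFAULT_ABC = fit_steinhart_hart(GENERIC_10K_RT_TRIPLE)


@dataclass(frozen=True)
class ThermistorCal:
    """Divider + Steinhart-Hart calibration for one thermistor channel."""

    sh_a: float = _DEFAULT_ABC[0]
    sh_b: float = _DEFAULT_ABC[1]
    sh_c: float = _DEFAULT_ABC[2]
    r_fixed: float = 10_000.0  # ohm
    v_ref: float = 2.5  # volt
    topology: DividerTopology = DividerTopology.THERMISTOR_BOTTOM

    def __post_init__(self):
        if self.r_fixed <= 0:
            raise DomainError(f"r_fixed must be > 0, got {self.r_fixed}")
        if self.v_ref <= 0:
            raise DomainError(f"v_ref must be > 0, got {self.v_ref}")


def adc_to_resistance(v_measured, cal: ThermistorCal | None = None):
    """Thermistor resistance (ohm) from the measured divider voltage (V).

    Accepts scalars or arrays.  Voltages at or outside (0, v_ref) indicate an
    open or shorted probe and raise :class:`OutOfRangeError`.
    """
    cal = cal or ThermistorCal()
    v = np.asarray(v_measured, dtype=float)
    if np.any(v <= 0.0) or np.any(v >= cal.v_ref):
        raise OutOfRangeError(
            f"voltage outside (0, {cal.v_ref}) V: open or shorted probe"
        )
    if cal.topology is DividerTopology.THERMISTOR_BOTTOM:
        r = cal.r_fixed * v / (cal.v_ref - v)
    else:
        r = cal.r_fixed * (cal.v_ref - v) / v
    return float(r) if np.isscalar(v_measured) else r


def resistance_to_temperature(r, cal: ThermistorCal | None = None):
    """Temperature (degC) from thermistor resistance (ohm), Steinhart-Hart."""
    cal = cal or ThermistorCal()
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0.0):
        raise DomainError("resistance must be > 0 ohm")
    ln_r = np.log(r_arr)
    inv_t = cal.sh_a + cal.sh_b * ln_r + cal.sh_c * ln_r**3
    t = 1.0 / inv_t - _ZERO_C
    return float(t) if np.isscalar(r) else t


def temperature_to_resistance(t_c, cal: ThermistorCal | None = None):
    """Invert Steinhart-Hart: resistance (ohm) at temperature (degC).

    Uses the closed-form solution of the depressed cubic in ln(R); needed by
    the simulator when it emits logger files in volts.
    """
    cal = cal or ThermistorCal()
    t = np.asarray(t_c, dtype=float)
    x = (cal.sh_a - 1.0 / (t + _ZERO_C)) / cal.sh_c
    y = np.sqrt((cal.sh_b / (3.0 * cal.sh_c)) ** 3 + (x / 2.0) ** 2)
    ln_r = np.cbrt(y - x / 2.0) - np.cbrt(y + x / 2.0)
    r = np.exp(ln_r)
    return float(r) if np.isscalar(t_c) else r


def voltage_to_temperature(v_measured, cal: ThermistorCal | None = None):
    """Compose the divider and Steinhart-Hart conversions."""
    cal = cal or ThermistorCal()
    return resistance_to_temperature(adc_to_resistance(v_measured, cal), cal)


def temperature_to_voltage(t_c, cal: ThermistorCal | None = None):
    """Divider voltage (V) that a thermistor at ``t_c`` degC would produce."""
    cal = cal or ThermistorCal()
    r = temperature_to_resistance(t_c, cal)
    if cal.topology is DividerTopology.THERMISTOR_BOTTOM:
        v = cal.v_ref * r / (r + cal.r_fixed)
    else:
        v = cal.v_ref * cal.r_fixed / (r + cal.r_fixed)
    return v
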