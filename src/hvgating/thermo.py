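"""Physical-chemistry utilities for proton-channel electrophysiology.

Thermal voltage, Nernst slope and the proton reversal potential are the
only thermodynamic quantities the analysis needs: the reversal potential
anchors the conductance transform G = I/(V - E_rev), and the thermal
voltage converts Boltzmann slope factors into apparent gating valences.

Units follow the package-wide convention: potentials in mV, temperatures
in kelvin. pH is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA 2018 values
GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1

#: Default recording temperature (~20 degC), at which RT/F rounds to 25.3 mV.
DEFAULT_TEMPERATURE_K = 293.15

__all__ = [
    "RecordingConditions",
    "thermal_voltage",
    "nernst_slope",
    "proton_reversal",
    "DEFAULT_TEMPERATURE_K",
]


@dataclass(frozen=True)
class RecordingConditions:
    """Ionic conditions of a whole-cell recording.

    Parameters
    ----------
    ph_i, ph_o
        Intracellular and extracellular pH. Both must lie in (0, 14).
    temperature
        Absolute temperature in kelvin; defaults to 293.15 K (~20 degC).
    """

    ph_i: float
    ph_o: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not 0.0 < self.ph_i < 14.0:
            raise ValueError(f"ph_i must lie in (0, 14), got {self.ph_i}")
        if not 0.0 < self.ph_o < 14.0:
            raise ValueError(f"ph_o must lie in (0, 14), got {self.ph_o}")
        if self.temperature <= 0.0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def delta_ph(self) -> float:
        """pH gradient pH_o - pH_i (negative when the bath is more acidic)."""
        return self.ph_o - self.ph_i


def thermal_voltage(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal voltage RT/F in mV.

    25.3 mV at 293.15 K; linear in absolute temperature.
    """
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1e3 * GAS_CONSTANT * temperature / FARADAY


def nernst_slope(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst slope (RT/F)·ln 10 in mV per pH (decade) unit.

    58.2 mV/pH unit at 293.15 K.
    """
    return thermal_voltage(temperature) * math.log(10.0)


def proton_reversal(conditions: RecordingConditions) -> float:
    """Nernst reversal potential for protons, in mV.

    E_H = (RT/F)·ln10 · (pH_i - pH_o): positive when the bath is more
    acidic than the pipette (inward proton gradient).
    """
    return nernst_slope(conditions.temperature) * (conditions.ph_i - conditions.ph_o)
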