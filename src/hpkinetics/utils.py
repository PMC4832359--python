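"""Closed-form arithmetic around the experiment: bolus dilution and the
DNP enhancement <-> polarization conversion."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "dilution_concentration",
    "thermal_polarization",
    "enhancement_to_polarization",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants for the thermal-polarization formula (CODATA 2018).

    gamma_13c : gyromagnetic ratio of 13C, rad/(s*T)
    hbar : reduced Planck constant, J*s
    k_boltzmann : Boltzmann constant, J/K
    """

    gamma_13c: float = 6.728284e7
    hbar: float = 1.054571817e-34
    k_boltzmann: float = 1.380649e-23

    def __post_init__(self) -> None:
        if min(self.gamma_13c, self.hbar, self.k_boltzmann) <= 0:
            raise ValueError("physical constants must be positive")


CODATA = PhysicalConstants()


def dilution_concentration(c_stock: float, flow_inject: float, flow_perfusate: float) -> float:
    """Concentration after mixing an injected stock into a perfusate line, mM.

    ``c_stock * flow_inject / (flow_inject + flow_perfusate)``; flows in any
    common unit (e.g. ml/min).
    """
    if flow_inject < 0 or flow_perfusate < 0:
        raise ValueError("flows must be >= 0")
    total = flow_inject + flow_perfusate
    if total == 0:
        raise ValueError("at least one flow must be positive")
    return c_stock * flow_inject / total


def thermal_polarization(B: float, T: float, constants: PhysicalConstants = CODATA) -> float:
    """Thermal-equilibrium 13C polarization ``hbar*gamma*B / (2*k*T)``.

    High-temperature (linear) approximation of ``tanh(hbar*gamma*B/(2*k*T))``,
    excellent at any laboratory field and temperature.
    """
    if B <= 0 or T <= 0:
        raise ValueError("field and temperature must be positive")
    return constants.hbar * constants.gamma_13c * B / (2.0 * constants.k_boltzmann * T)


def enhancement_to_polarization(enhancement: float, B: float = 9.4, T: float = 310.0,
                                constants: PhysicalConstants = CODATA) -> float:
    """Polarization fraction implied by a DNP signal enhancement.

    The enhancement multiplies the thermal polarization at the measurement
    field and temperature (defaults: 9.4 T, 310 K).
    """
    if enhancement <= 0:
        raise ValueError("enhancement must be positive")
    return enhancement * thermal_polarization(B, T, constants)
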