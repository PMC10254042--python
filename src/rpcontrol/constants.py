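"""Physical constants and unit conversions.

Internal energy unit throughout the package is angular frequency in
rad/us (microseconds are the natural time unit for radical-pair
kinetics at mT fields).  All user-facing parameters are magnetic flux
density in mT or linear frequency in MHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import physical_constants

_MU_B = physical_constants["Bohr magneton"][0]  # J/T
_MU_N = physical_constants["nuclear magneton"][0]  # J/T
_HBAR = physical_constants["reduced Planck constant"][0]  # J*s
_H = physical_constants["Planck constant"][0]  # J*s

#: Nuclear g-factor of the proton (the model never states one; the
#: nuclear Zeeman term is negligible below ~20 mT but kept for fidelity).
PROTON_G = 5.5856946893

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values used by the Hamiltonian builders."""

    bohr_magneton: float = _MU_B
    nuclear_magneton: float = _MU_N
    hbar: float = _HBAR
    planck: float = _H

    def __post_init__(self) -> None:
        for name in ("bohr_magneton", "nuclear_magneton", "hbar", "planck"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicalConstants()


def electron_gyromagnetic(g: float) -> float:
    """g * mu_B / hbar expressed in rad/us per mT."""
    return g * CONSTANTS.bohr_magneton / CONSTANTS.hbar * 1e-9


def nuclear_gyromagnetic(g_n: float) -> float:
    """g_N * mu_N / hbar expressed in rad/us per mT."""
    return g_n * CONSTANTS.nuclear_magneton / CONSTANTS.hbar * 1e-9


def mT_to_rad_per_us(b_mT: float, g: float) -> float:
    """Convert a field/coupling in mT to angular frequency (rad/us)."""
    return electron_gyromagnetic(g) * b_mT


def rad_per_us_to_mT(omega: float, g: float) -> float:
    return omega / electron_gyromagnetic(g)


def MHz_to_rad_per_us(f_MHz: float) -> float:
    """Linear frequency in MHz to angular frequency in rad/us."""
    return TWO_PI * f_MHz


def rad_per_us_to_MHz(omega: float) -> float:
    return omega / TWO_PI


def mT_to_MHz(b_mT: float, g: float) -> float:
    """Field-equivalent coupling in mT to linear frequency in MHz."""
    return rad_per_us_to_MHz(mT_to_rad_per_us(b_mT, g))


def MHz_to_mT(f_MHz: float, g: float) -> float:
    return rad_per_us_to_mT(MHz_to_rad_per_us(f_MHz), g)
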