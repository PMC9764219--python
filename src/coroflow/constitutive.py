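"""Blood rheology and the vessel-wall tube law.

Blood is an incompressible Newtonian fluid; its dynamic viscosity is
derived from hematocrit by the empirical relation ``mu = mu0 / (1 - phi)``
with plasma viscosity ``mu0`` (1.2 cP by default).  The wall is closed by
the algebraic square-root tube law

    P = Pext + beta * (sqrt(A) - sqrt(A0)),
    beta = sqrt(pi) * h * E / ((1 - nu^2) * A0),

whose characteristic wave speed is ``c = sqrt(beta * sqrt(A) / (2 rho))``.
The friction term of the momentum equation uses the kinematic coefficient
``Cf = 22 pi mu / rho`` paired with momentum-flux correction
``alpha = 1.1`` (a blunted polynomial velocity profile); both are
config-exposed.  The physical defaults (h = 0.945 mm, E = 1.41 MPa,
nu = 0.5) give a quasi-rigid wall at coronary pressures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .units import CP_TO_PAS


def blood_viscosity(mu0_cP: float = 1.2, hematocrit: float = 0.392) -> float:
    """Dynamic blood viscosity (cP) from plasma viscosity and hematocrit.

    ``mu = mu0 / (1 - phi)`` with ``phi`` the hematocrit fraction in
    [0, 1).  With the defaults (1.2 cP plasma, 39.2% hematocrit) this
    gives 1.97 cP.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise DomainError(f"hematocrit fraction {hematocrit} outside [0, 1)")
    if mu0_cP <= 0:
        raise DomainError("plasma viscosity must be > 0")
    return mu0_cP / (1.0 - hematocrit)


@dataclass(frozen=True)
class BloodProperties:
    """Fluid constants for the 1D momentum equation (SI internally)."""

    rho: float = 1060.0          # kg/m^3
    mu0_cP: float = 1.2          # plasma viscosity, cP
    hematocrit: float = 0.392    # fraction
    alpha: float = 1.1           # momentum-flux correction

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise DomainError("density must be > 0")
        if self.alpha < 1.0:
            raise DomainError("alpha must be >= 1")
        blood_viscosity(self.mu0_cP, self.hematocrit)  # domain checks

    @property
    def mu_cP(self) -> float:
        return blood_viscosity(self.mu0_cP, self.hematocrit)

    @property
    def mu(self) -> float:
        """Dynamic viscosity, Pa*s."""
        return self.mu_cP * CP_TO_PAS

    @property
    def Cf(self) -> float:
        """Kinematic friction coefficient, m^2/s (22 pi nu)."""
        return 22.0 * math.pi * self.mu / self.rho

    def with_hematocrit(self, hematocrit: float) -> "BloodProperties":
        return replace(self, hematocrit=hematocrit)


@dataclass(frozen=True)
class WallLaw:
    """Tube-law parameters (clinical units in, SI out)."""

    h_mm: float = 0.945          # wall thickness
    E_MPa: float = 1.41          # elastic modulus
    nu: float = 0.5              # Poisson ratio
    Pext: float = 0.0            # external pressure, Pa
    stiffness_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 0.5:
            raise DomainError("Poisson ratio must be in (0, 0.5]")
        if self.h_mm <= 0 or self.E_MPa <= 0 or self.stiffness_multiplier <= 0:
            raise DomainError("h, E, stiffness multiplier must be > 0")

    def beta(self, A0):
        """Stiffness beta(A0) in Pa/m for reference area A0 in m^2."""
        A0 = np.asarray(A0, dtype=float)
        if np.any(A0 <= 0):
            raise DomainError("reference area must be > 0")
        h = self.h_mm * 1e-3
        E = self.E_MPa * 1e6
        return (math.sqrt(math.pi) * h * E / ((1.0 - self.nu ** 2) * A0)
                * self.stiffness_multiplier)


def tube_law(A, A0, wall: WallLaw = WallLaw()):
    """Transmural pressure P(A) in Pa (areas in m^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DomainError("area must be > 0")
    beta = wall.beta(A0)
    return wall.Pext + beta * (np.sqrt(A) - np.sqrt(np.asarray(A0, float)))


def tube_law_area(P, A0, wall: WallLaw = WallLaw()):
    """Inverse tube law A(P); raises if P implies non-physical area."""
    beta = wall.beta(A0)
    root = (np.asarray(P, float) - wall.Pext) / beta + np.sqrt(
        np.asarray(A0, float))
    if np.any(root <= 0):
        raise DomainError("pressure implies non-physical (<= 0) area")
    return root ** 2


def wave_speed(A, A0, rho: float = 1060.0, wall: WallLaw = WallLaw()):
    """Characteristic pulse-wave speed c = sqrt(beta sqrt(A) / (2 rho))."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DomainError("area must be > 0")
    return np.sqrt(wall.beta(A0) * np.sqrt(A) / (2.0 * rho))
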