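"""Marangoni and dialytaxis predictors.

Droplets in an interfacial-tension gradient develop internal circulation and
swim down the gradient; for an idealized Marangoni swimmer in an unbounded
linear gradient the maximum internal speed is V_m = |Delta gamma| / (6 eta),
with Delta gamma = 2 R (dgamma/dpH)(dpH/dx) when the gradient acts through
the pH.  The dialytaxis argument couples interfacial tension to the phase
diagram, gamma ~ (phi_m/phi_c - 1)^nu with the mean-field exponent nu = 3/2,
so that a solute which shifts the critical point phi_c toward the overall
composition lowers gamma and attracts droplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "MarangoniInput",
    "PhaseDiagramModel",
    "internal_speed_max",
    "swim_direction",
    "delta_gamma_across_drop",
    "tension_from_phase_diagram",
    "dialytaxis_velocity_scale",
    "peclet",
    "ParameterBox",
    "peclet_bounds",
]


@dataclass(frozen=True)
class PhysicalConstants:
    k_B: float = 1.380649e-23  # J/K
    T: float = 298.15  # K
    g: float = 9.81  # m/s^2

    @property
    def kT(self) -> float:
        return self.k_B * self.T


@dataclass(frozen=True)
class MarangoniInput:
    """Inputs of the idealized-swimmer speed prediction."""

    eta: float  # Pa s, viscosity of the more viscous phase
    R: float  # m
    dgamma_dpH: float = 0.0  # N/m per pH unit
    dpH_dx: float = 0.0  # pH per m

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.R <= 0:
            raise ValueError("eta and R must be positive")

    @property
    def delta_gamma(self) -> float:
        return delta_gamma_across_drop(self.R, self.dgamma_dpH, self.dpH_dx)

    @property
    def v_max(self) -> float:
        return internal_speed_max(self.delta_gamma, self.eta)


def internal_speed_max(delta_gamma: float, eta: float) -> float:
    """Maximum internal speed |Delta gamma| / (6 eta) of a Marangoni swimmer."""
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return abs(delta_gamma) / (6.0 * eta)


def swim_direction(delta_gamma_gradient_sign: float) -> int:
    """Sign of the swim velocity along +x: droplets swim down the
    interfacial-tension gradient."""
    return -int(math.copysign(1, delta_gamma_gradient_sign)) if delta_gamma_gradient_sign else 0


def delta_gamma_across_drop(R: float, dgamma_dpH: float, dpH_dx: float) -> float:
    """Signed tension difference 2 R (dgamma/dpH)(dpH/dx) across a drop."""
    if R <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * R * dgamma_dpH * dpH_dx


@dataclass(frozen=True)
class PhaseDiagramModel:
    """Interfacial tension from the distance to the critical point.

    gamma = prefactor (phi_m/phi_c - 1)^nu, phi_c the macromolecule
    concentration at the critical point, phi_m at the tie-line center, in any
    consistent concentration units.  ``dphic_dc`` is the susceptibility of
    the critical point to a solute (phi units per mol/m^3).
    """

    phi_c: float
    phi_m: float
    nu: float = 1.5
    prefactor: float = 1.0  # N/m scale
    dphic_dc: float = 0.0

    def __post_init__(self) -> None:
        if self.phi_c <= 0:
            raise ValueError("phi_c must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be positive")

    @property
    def mixed(self) -> bool:
        """True when the overall state is single-phase (phi_m below phi_c)."""
        return self.phi_m < self.phi_c


def tension_from_phase_diagram(m: PhaseDiagramModel) -> float:
    """gamma = prefactor (phi_m/phi_c - 1)^nu; zero in the mixed state."""
    if m.mixed:
        return 0.0
    return m.prefactor * (m.phi_m / m.phi_c - 1.0) ** m.nu


def dialytaxis_velocity_scale(
    R: float, eta: float, dphic_dc: float, dc_dx: float, prefactor: float = 1.0
) -> float:
    """Dialytactic swim-velocity scale (R/eta)(dphi_c/dc)(dc/dx).

    Positive means motion up the solute gradient (a solute that raises the
    critical point dissolves droplets and attracts them); the returned value
    is a scale, not a calibrated speed.
    """
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return prefactor * (R / eta) * dphic_dc * dc_dx


def peclet(
    eta_ratio: float,
    R: float,
    delta_gamma: float,
    consts: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Pe = (eta_dilute/eta) pi R^2 Delta gamma / kT for a dialytactic drop.

    ``eta_ratio`` is eta_dilute/eta (< 1 for viscous condensates).
    """
    if eta_ratio <= 0 or R <= 0 or delta_gamma < 0:
        raise ValueError("inputs must be positive (delta_gamma non-negative)")
    return eta_ratio * math.pi * R**2 * delta_gamma / consts.kT


@dataclass(frozen=True)
class ParameterBox:
    """Literature ranges of condensate properties for the Peclet estimate.

    ``visc_contrast`` is eta/eta_dilute; ``delta_gamma`` is taken as the
    stated fraction of gamma (moderate perturbation of the phase
    equilibrium).
    """

    visc_contrast: tuple = (10.0, 100.0)
    gamma: tuple = (0.1e-6, 100e-6)  # N/m
    radius: tuple = (0.5e-6, 10e-6)  # m
    dgamma_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("visc_contrast", "gamma", "radius"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def peclet_bounds(
    box: ParameterBox = ParameterBox(),
    consts: PhysicalConstants = PhysicalConstants(),
) -> tuple:
    """(Pe_min, Pe_max) over the parameter box.

    Pe is monotone in every argument, so the extremes sit at the box corners:
    the minimum at high viscosity contrast, small radius and low tension, the
    maximum at the opposite corner.
    """
    pe_min = peclet(
        1.0 / box.visc_contrast[1],
        box.radius[0],
        box.dgamma_fraction * box.gamma[0],
        consts,
    )
    pe_max = peclet(
        1.0 / box.visc_contrast[0],
        box.radius[1],
        box.dgamma_fraction * box.gamma[1],
        consts,
    )
    return pe_min, pe_max
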