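"""Chemical data model for the urease-loaded condensate micro-reactor.

The droplet converts urea into ammonia and carbon dioxide, which speciate
through fast acid--base equilibria with the phosphate buffer and water.  This
module holds the species table (diffusivities, far-field composition), the
equilibrium constants, the Michaelis--Menten enzyme kinetics, and the two
spatial modifiers shared with the solver: the smooth partitioning step S(r)
and the obstruction-theory diffusivity scaling.

Internal unit system is strict SI: concentrations in mol/m^3 (numerically
equal to mM), lengths in m, viscosities in Pa s.  pKa values are defined on
the conventional molar scale and converted internally (1 M = 1000 mol/m^3).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SPECIES_NAMES",
    "DEFAULT_D_WATER",
    "M_PER_M3",
    "SpeciesTable",
    "EquilibriumConstants",
    "EnzymeKinetics",
    "PhasePair",
    "parse_quantity",
    "speciation",
    "far_field_state",
    "mm_rate",
    "obstruction_diffusivity",
    "smooth_step",
]

# Species order used throughout: urea, NH3, NH4+, CO2, HCO3-, H+, OH-,
# HPO4^2-, H2PO4-.  Indices are 0-based; the field convention numbers them
# 1..9 in the same order.
SPECIES_NAMES = (
    "urea",
    "NH3",
    "NH4+",
    "CO2",
    "HCO3-",
    "H+",
    "OH-",
    "HPO4^2-",
    "H2PO4-",
)

# Diffusivities in pure water, m^2/s (small-molecule literature values).
DEFAULT_D_WATER = np.array(
    [1.38e-9, 1.50e-9, 1.96e-9, 1.67e-9, 1.19e-9, 9.31e-9, 5.27e-9, 0.76e-9, 0.96e-9]
)

#: mol/m^3 per mol/L
M_PER_M3 = 1000.0

_UNIT_FACTORS = {
    # concentration -> mol/m^3
    "M": 1000.0,
    "mM": 1.0,
    "uM": 1e-3,
    "nM": 1e-6,
    "mol/m3": 1.0,
    # length -> m
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "nm": 1e-9,
    # viscosity -> Pa s
    "Pa.s": 1.0,
    "mPa.s": 1e-3,
    # rate -> 1/s
    "1/s": 1.0,
    # diffusivity -> m^2/s
    "m2/s": 1.0,
    "um2/s": 1e-12,
}


def parse_quantity(value: "float | str") -> float:
    """Convert a ``"100 mM"``-style tagged quantity to SI.

    Bare numbers are taken to be SI already.  Unit tags are explicit because
    the natural inputs mix mM, uM, um and mPa s.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([A-Za-z0-9./]+)\s*", str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNIT_FACTORS[unit]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Acid dissociation constants of the fast proton-exchange reactions.

    ``Ka2`` (NH4+/NH3), ``Ka3`` (CO2/HCO3-) and ``Ka5`` (H2PO4-/HPO4^2-) are
    concentration ratios in mol/m^3; ``Kw`` is the water autoprotolysis
    product c_H * c_OH in (mol/m^3)^2.
    """

    Ka2: float
    Ka3: float
    Kw: float
    Ka5: float

    @classmethod
    def from_pka(
        cls,
        pKa2: float = 9.25,
        pKa3: float = 6.35,
        pKw: float = 14.0,
        pKa5: float = 7.21,
    ) -> "EquilibriumConstants":
        """Build from molar-scale pKa values (the conventional scale)."""
        return cls(
            Ka2=10.0 ** (-pKa2) * M_PER_M3,
            Ka3=10.0 ** (-pKa3) * M_PER_M3,
            Kw=10.0 ** (-pKw) * M_PER_M3**2,
            Ka5=10.0 ** (-pKa5) * M_PER_M3,
        )

    def __post_init__(self) -> None:
        for name in ("Ka2", "Ka3", "Kw", "Ka5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pka(self) -> dict:
        """Round-trip back to molar-scale pKa values."""
        return {
            "pKa2": -math.log10(self.Ka2 / M_PER_M3),
            "pKa3": -math.log10(self.Ka3 / M_PER_M3),
            "pKw": -math.log10(self.Kw / M_PER_M3**2),
            "pKa5": -math.log10(self.Ka5 / M_PER_M3),
        }


@dataclass(frozen=True)
class SpeciesTable:
    """Per-species diffusivity in water and far-field concentration."""

    D_w: np.ndarray  # (9,) m^2/s
    c_inf: np.ndarray  # (9,) mol/m^3
    names: Sequence[str] = SPECIES_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "D_w", np.asarray(self.D_w, dtype=float))
        object.__setattr__(self, "c_inf", np.asarray(self.c_inf, dtype=float))
        if self.D_w.shape != (9,) or self.c_inf.shape != (9,):
            raise ValueError("SpeciesTable requires exactly 9 species")
        if np.any(self.D_w <= 0):
            raise ValueError("all diffusivities must be positive")
        if np.any(self.c_inf < 0):
            raise ValueError("far-field concentrations must be non-negative")

    def validate_equilibrium(self, eq: EquilibriumConstants, rtol: float = 1e-9) -> None:
        """Check the far field against every equilibrium closure."""
        c = self.c_inf
        checks = {
            "NH3/NH4+": (c[1] * c[5], eq.Ka2 * c[2]),
            "CO2/HCO3-": (c[4] * c[5], eq.Ka3 * c[3]),
            "water": (c[5] * c[6], eq.Kw),
            "phosphate": (c[7] * c[5], eq.Ka5 * c[8]),
        }
        for label, (lhs, rhs) in checks.items():
            scale = max(abs(lhs), abs(rhs))
            if scale > 0 and abs(lhs - rhs) > rtol * scale:
                raise ValueError(
                    f"far field violates {label} equilibrium: {lhs:g} vs {rhs:g}"
                )


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis--Menten kinetics of the droplet-partitioned urease.

    ``c_e_dense`` is the enzyme concentration inside the dense phase.  With
    infinite partitioning it relates to the overall loading by
    c_e_dense = c_e_overall / phi_d, phi_d the condensate volume fraction.
    """

    k_cat: float  # 1/s
    K_m: float  # mol/m^3
    c_e_dense: float  # mol/m^3

    def __post_init__(self) -> None:
        if self.k_cat < 0:
            raise ValueError("k_cat must be non-negative")
        if self.K_m <= 0 or self.c_e_dense <= 0:
            raise ValueError("K_m and c_e_dense must be positive")

    @classmethod
    def from_overall(
        cls, k_cat: float, K_m: float, c_e_overall: float, phi_d: float
    ) -> "EnzymeKinetics":
        if not 0 < phi_d <= 1:
            raise ValueError("phi_d must lie in (0, 1]")
        return cls(k_cat=k_cat, K_m=K_m, c_e_dense=c_e_overall / phi_d)

    def with_k_cat(self, k_cat: float) -> "EnzymeKinetics":
        return replace(self, k_cat=k_cat)


@dataclass(frozen=True)
class PhasePair:
    """Viscosities of the two coexisting phases and the droplet geometry."""

    eta_dense: float  # Pa s
    eta_dilute: float = 24e-3  # Pa s
    eta_water: float = 1e-3  # Pa s
    R: float = 25e-6  # m
    sharpness: float = 100.0  # dimensionless step factor

    def __post_init__(self) -> None:
        if not (self.eta_dense >= self.eta_dilute >= self.eta_water > 0):
            raise ValueError("require eta_dense >= eta_dilute >= eta_water > 0")
        if self.R <= 0:
            raise ValueError("droplet radius must be positive")

    def with_radius(self, R: float) -> "PhasePair":
        return replace(self, R=R)


def speciation(total, c_H, Ka):
    """Split an acid/base total into (protonated, deprotonated) at given H+.

    deprotonated / protonated = Ka / c_H, and the two parts sum to ``total``
    exactly (the deprotonated part is computed as the remainder).
    Vectorized over any argument.
    """
    total = np.asarray(total, dtype=float)
    c_H = np.asarray(c_H, dtype=float)
    Ka = np.asarray(Ka, dtype=float)
    if np.any(total < 0):
        raise ValueError("total concentration must be non-negative")
    if np.any(c_H <= 0) or np.any(Ka <= 0):
        raise ValueError("c_H and Ka must be positive")
    protonated = total * (c_H / (c_H + Ka))
    deprotonated = total - protonated
    if total.ndim == 0:
        return float(protonated), float(deprotonated)
    return protonated, deprotonated


def far_field_state(
    pH_inf: float,
    total_phosphate: float,
    c_s: float,
    eq: EquilibriumConstants | None = None,
    D_w: np.ndarray | None = None,
) -> SpeciesTable:
    """Far-field composition: urea at c_s, no products, buffered at pH_inf.

    H+ follows from the pH (molar scale), OH- from the water product, and the
    phosphate total is split across HPO4^2-/H2PO4- by its pKa.
    """
    if not 0 < pH_inf < 14:
        raise ValueError(f"pH_inf={pH_inf} outside the physical range (0, 14)")
    if total_phosphate < 0 or c_s < 0:
        raise ValueError("totals must be non-negative")
    eq = eq or EquilibriumConstants.from_pka()
    c6 = 10.0 ** (-pH_inf) * M_PER_M3
    c7 = eq.Kw / c6
    c9, c8 = speciation(total_phosphate, c6, eq.Ka5)  # (H2PO4-, HPO4^2-)
    c_inf = np.array([c_s, 0.0, 0.0, 0.0, 0.0, c6, c7, c8, c9])
    table = SpeciesTable(
        D_w=DEFAULT_D_WATER if D_w is None else D_w, c_inf=c_inf
    )
    table.validate_equilibrium(eq)
    return table


def mm_rate(c1, kin: EnzymeKinetics):
    """Volumetric Michaelis--Menten urea consumption rate, mol/m^3/s."""
    c1 = np.asarray(c1, dtype=float)
    if np.any(c1 < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = kin.k_cat * kin.c_e_dense * c1 / (kin.K_m + c1)
    return float(out) if out.ndim == 0 else out


def obstruction_diffusivity(D_w, eta, eta_w: float = 1e-3):
    """Small-molecule diffusivity in a crowded phase of viscosity ``eta``.

    Obstruction theory gives D = D_w (eta/eta_w)^(-3/5), a much weaker
    suppression than Stokes--Einstein because the diffusing solutes are far
    smaller than the macromolecules setting the bulk viscosity.
    """
    D_w = np.asarray(D_w, dtype=float)
    if np.any(D_w <= 0) or eta <= 0 or eta_w <= 0:
        raise ValueError("all inputs must be positive")
    out = D_w * (eta / eta_w) ** (-0.6)
    return float(out) if out.ndim == 0 else out


def smooth_step(r, pp: PhasePair):
    """Smoothed droplet indicator S(r) = (1 - tanh(s (r-R)/R)) / 2.

    Equals 1 deep inside the drop, 1/2 at r = R, and 0 outside; used both for
    the enzyme localization c_e(r) = c_e_dense S(r) and to interpolate each
    diffusivity between its dense- and dilute-phase values.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    out = 0.5 * (1.0 - np.tanh(pp.sharpness * (r - pp.R) / pp.R))
    return float(out) if out.ndim == 0 else out
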