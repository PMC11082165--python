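"""Steady-state spherically symmetric solver for the droplet micro-reactor.

The nine species of the urease reaction network reduce to five independent
fields: urea c1, total ammonia N = c2 + c3, total inorganic carbon
C = c4 + c5, total phosphate P = c8 + c9, and the proton concentration c6.
Four flux combinations are divergence-free (the fast proton-exchange source
terms cancel identically), and the four acid--base closures recover the full
nine-species state pointwise.

The solver discretizes the five transport equations with a conservative
finite-volume scheme on a stretched radial grid (refined across the smoothed
droplet edge), imposes symmetry at r = 0 through the vanishing inner-face
area and Dirichlet far-field values at r_max, and solves the nonlinear
system with damped Newton iterations on (c1, N, C, P, log c6).  A k_cat
continuation ramp is used as a fallback for strongly reacting droplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .reaction_network import (
    M_PER_M3,
    EnzymeKinetics,
    EquilibriumConstants,
    PhasePair,
    SpeciesTable,
    obstruction_diffusivity,
    smooth_step,
    speciation,
)

__all__ = [
    "RDProblem",
    "RadialProfile",
    "DamkohlerSweepResult",
    "ThresholdResult",
    "SolverError",
    "assemble_unknowns",
    "reconstruct_species",
    "solve_steady_state",
    "shell_flux",
    "integrated_reaction_rate",
    "damkohler",
    "dense_phase_D1",
    "sweep_radius",
    "threshold_da",
]

# Combined-flux weights w_kj such that the combination sum_j w_kj (-D_j grad c_j)
# is divergence-free (except urea, which carries the enzymatic sink).
_COMBO_WEIGHTS = {
    "urea": {0: 1.0},
    "nitrogen": {1: 1.0, 2: 1.0, 0: 2.0},
    "carbon": {3: 1.0, 4: 1.0, 0: 1.0},
    "charge": {5: 1.0, 2: 1.0, 4: -1.0, 6: -1.0, 7: -1.0},
    "phosphate": {7: 1.0, 8: 1.0},
}
CONSERVED_COMBOS = ("nitrogen", "carbon", "charge", "phosphate")


class SolverError(RuntimeError):
    """Raised when the damped-Newton iteration fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class RDProblem:
    """Full parameterization of one steady-state droplet solve."""

    species: SpeciesTable
    equilibria: EquilibriumConstants
    kinetics: EnzymeKinetics
    phases: PhasePair
    domain_factor: float = 50.0
    n_nodes: int = 260
    tol: float = 1e-8
    max_newton: int = 60

    def __post_init__(self) -> None:
        if self.domain_factor < 10:
            raise ValueError("domain_factor must be at least 10")
        if self.n_nodes < 60:
            raise ValueError("grid too coarse")
        self.species.validate_equilibrium(self.equilibria)

    def with_radius(self, R: float) -> "RDProblem":
        return replace(self, phases=self.phases.with_radius(R))


def radial_grid(
    R: float, domain_factor: float, n_nodes: int, sharpness: float
) -> np.ndarray:
    """Stretched node positions: fine uniform band across the droplet edge
    (spacing <= R / (2 sharpness) within |r - R| <= 0.2 R), geometric
    stretching toward the center and the far field."""
    h_fine = R / (2.0 * sharpness)
    n_band = max(int(math.ceil(0.4 * R / h_fine)), int(round(0.37 * n_nodes)))
    n_inner = max(16, int(round(0.18 * n_nodes)))
    n_outer = max(24, n_nodes - n_band - n_inner)

    band = np.linspace(0.8 * R, 1.2 * R, n_band + 1)
    inner = _geometric_segment(0.0, 0.8 * R, h_small=band[1] - band[0],
                               n=n_inner, fine_end="b")
    outer = _geometric_segment(1.2 * R, domain_factor * R,
                               h_small=band[1] - band[0], n=n_outer,
                               fine_end="a")
    return np.concatenate([inner[:-1], band, outer[1:]])


def _geometric_segment(a: float, b: float, h_small: float, n: int, fine_end: str):
    """n+1 points on [a, b] with geometrically growing spacing away from the
    fine end, whose spacing is ~h_small (uniform if that already suffices)."""
    length = b - a
    if h_small * n >= length:
        return np.linspace(a, b, n + 1)

    def gap(q):
        return h_small * (q**n - 1.0) / (q - 1.0) - length

    q = brentq(gap, 1.0 + 1e-12, 10.0, xtol=1e-14)
    spac = h_small * q ** np.arange(n)
    cum = np.concatenate([[0.0], np.cumsum(spac)])
    cum *= length / cum[-1]
    if fine_end == "a":
        return a + cum
    return b - cum[::-1]


def reconstruct_species(u: np.ndarray, eq: EquilibriumConstants) -> np.ndarray:
    """Map reduced fields (5, N) -> full species concentrations (9, N)."""
    c1, N, C, P, c6 = u
    c6 = np.asarray(c6, dtype=float)
    c3, c2 = speciation(N, c6, eq.Ka2)
    c4, c5 = speciation(C, c6, eq.Ka3)
    c9, c8 = speciation(P, c6, eq.Ka5)
    c7 = eq.Kw / c6
    return np.array([c1, c2, c3, c4, c5, c6, c7, c8, c9])


def assemble_unknowns(
    c: np.ndarray, eq: EquilibriumConstants, rtol: float = 1e-6
) -> np.ndarray:
    """Map full species state (9, ...) to the reduced fields (5, ...).

    Verifies the acid--base closures first; a violation above ``rtol``
    raises with the worst residual and its location.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float).T).T  # ensure (9, N)
    resids = np.array(
        [
            np.abs(c[1] * c[5] - eq.Ka2 * c[2])
            / np.maximum(np.maximum(c[1] * c[5], eq.Ka2 * c[2]), 1e-300),
            np.abs(c[4] * c[5] - eq.Ka3 * c[3])
            / np.maximum(np.maximum(c[4] * c[5], eq.Ka3 * c[3]), 1e-300),
            np.abs(c[5] * c[6] - eq.Kw) / eq.Kw,
            np.abs(c[7] * c[5] - eq.Ka5 * c[8])
            / np.maximum(np.maximum(c[7] * c[5], eq.Ka5 * c[8]), 1e-300),
        ]
    )
    # a zero total trivially satisfies its ratio closure
    totals = np.array([c[1] + c[2], c[3] + c[4], np.ones_like(c[0]), c[7] + c[8]])
    resids = np.where(totals > 0, resids, 0.0)
    worst = np.unravel_index(np.argmax(resids), resids.shape)
    if resids[worst] > rtol:
        raise ValueError(
            f"closure {worst[0]} violated at node {worst[1]}: "
            f"relative residual {resids[worst]:.3e}"
        )
    out = np.array([c[0], c[1] + c[2], c[3] + c[4], c[7] + c[8], c[5]])
    return out.squeeze()


@dataclass
class RadialProfile:
    """Converged radial solution with diagnostics."""

    r: np.ndarray  # (N,) m
    c: np.ndarray  # (9, N) mol/m^3
    converged: float  # final scaled residual rms
    problem: RDProblem
    conserved_flux: np.ndarray = field(init=False)  # (4, N) mol/s at nodes

    def __post_init__(self) -> None:
        self.conserved_flux = np.array(
            [
                np.interp(self.r, *_combo_shell_flux(self, combo))
                for combo in CONSERVED_COMBOS
            ]
        )

    @property
    def pH(self) -> np.ndarray:
        return -np.log10(self.c[5] / M_PER_M3)

    def ph_at(self, r: float) -> float:
        return float(np.interp(r, self.r, self.pH))

    @property
    def ph_center(self) -> float:
        return float(self.pH[0])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"r_m": self.r}
        for i in range(9):
            data[f"c{i + 1}"] = self.c[i]
        data["pH"] = self.pH
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# discretization internals


class _Discretization:
    """Grid geometry, face diffusivities and residual assembly for one solve."""

    def __init__(self, p: RDProblem):
        self.p = p
        self.r = radial_grid(
            p.phases.R, p.domain_factor, p.n_nodes, p.phases.sharpness
        )
        self.n = self.r.size
        r = self.r
        self.faces = 0.5 * (r[:-1] + r[1:])
        self.dr = np.diff(r)
        f3 = np.concatenate([[0.0], self.faces**3, [r[-1] ** 3]])
        self.vol = (f3[1:] - f3[:-1]) / 3.0  # per node, 4*pi dropped throughout
        self.area = np.concatenate([self.faces**2, [r[-1] ** 2]])

        # diffusivity of each species at faces: dense/dilute values blended
        # with the same smooth step used for the enzyme
        ph = p.phases
        D_dense = obstruction_diffusivity(p.species.D_w, ph.eta_dense, ph.eta_water)
        D_dilute = obstruction_diffusivity(p.species.D_w, ph.eta_dilute, ph.eta_water)
        S_f = smooth_step(self.faces, ph)
        self.D_face = D_dilute[:, None] + (D_dense - D_dilute)[:, None] * S_f
        self.S_node = smooth_step(r, ph)

        # far-field reduced state and characteristic scales
        eq = p.equilibria
        self.u_inf = assemble_unknowns(p.species.c_inf, eq)
        c_s = max(self.u_inf[0], 1e-9)
        self.char = np.array(
            [
                max(c_s, p.kinetics.K_m),
                c_s,
                c_s,
                max(self.u_inf[3], 1.0),
                1.0,  # log c6 is already O(1)
            ]
        )
        D_dil_combo = {
            k: max(D_dilute[j] for j in w) for k, w in _COMBO_WEIGHTS.items()
        }
        R2 = ph.R**2
        conc_char = [
            self.char[0],
            self.char[1],
            self.char[2],
            max(self.u_inf[3], self.u_inf[4] * 10, 1e-4),
            self.char[3],
        ]
        self.eq_scale = np.array(
            [
                D_dil_combo["urea"] * conc_char[0] / R2,
                D_dil_combo["nitrogen"] * conc_char[1] / R2,
                D_dil_combo["carbon"] * conc_char[2] / R2,
                D_dil_combo["charge"] * conc_char[3] / R2,
                D_dil_combo["phosphate"] * conc_char[4] / R2,
            ]
        )

    # -- state transforms ---------------------------------------------------

    def pack(self, c1, N, C, P, c6):
        return np.array([c1, N, C, P, np.log(c6)])

    def far_field_state(self):
        u = np.empty((5, self.n))
        u[0] = self.u_inf[0]
        u[1] = self.u_inf[1]
        u[2] = self.u_inf[2]
        u[3] = self.u_inf[3]
        u[4] = math.log(self.u_inf[4])
        return u

    def species_of(self, u):
        v = u.copy()
        v[4] = np.exp(np.clip(u[4], math.log(1e-12), math.log(1e3)))
        return reconstruct_species(v, self.p.equilibria)

    def residual(self, u, k_cat=None):
        """Scaled residual of the 5 transport equations, shape (5, N)."""
        p = self.p
        k_cat = p.kinetics.k_cat if k_cat is None else k_cat
        c = self.species_of(u)
        grad = (c[:, 1:] - c[:, :-1]) / self.dr  # (9, N-1) at faces
        F = -self.D_face * grad  # outward flux density per species

        res = np.empty((5, self.n))
        src = (
            k_cat
            * p.kinetics.c_e_dense
            * self.S_node
            * c[0]
            / (p.kinetics.K_m + c[0])
        )
        for k, name in enumerate(("urea", "nitrogen", "carbon", "charge", "phosphate")):
            J = sum(w * F[j] for j, w in _COMBO_WEIGHTS[name].items())
            AJ = np.concatenate([[0.0], self.area[:-1] * J])
            div = (np.concatenate([AJ[1:], [0.0]]) - AJ) / self.vol
            res[k] = div
            if name == "urea":
                res[k] += src
            elif name == "nitrogen":
                res[k] -= 0.0  # sources cancel by construction
            res[k] /= self.eq_scale[k]

        # Dirichlet far field at the last node
        res[0, -1] = (u[0, -1] - self.u_inf[0]) / self.char[0]
        res[1, -1] = (u[1, -1] - self.u_inf[1]) / self.char[1]
        res[2, -1] = (u[2, -1] - self.u_inf[2]) / self.char[2]
        res[3, -1] = (u[3, -1] - self.u_inf[3]) / self.char[3]
        res[4, -1] = u[4, -1] - math.log(self.u_inf[4])
        return res

    # -- Newton machinery ---------------------------------------------------

    def _fd_jacobian(self, u, res0, k_cat):
        n = self.n
        base_eps = np.array(
            [1e-6 * self.char[0], 1e-6 * self.char[1], 1e-6 * self.char[2],
             1e-6 * self.char[3], 1e-7]
        )
        rows, cols, vals = [], [], []
        i = np.arange(n)
        for color in range(3):
            j = i + ((color - i + 1) % 3) - 1  # perturbed node in each stencil
            j = np.clip(j, 0, n - 1)
            nodes = np.arange(color, n, 3)
            for k in range(5):
                eps_full = base_eps[k] + 1e-8 * np.abs(u[k])
                du = np.zeros_like(u)
                du[k, nodes] = eps_full[nodes]
                r1 = self.residual(u + du, k_cat)
                diff = (r1 - res0).T  # (N, 5) rows per node
                deriv = diff / eps_full[j][:, None]
                rows.append(np.repeat(i * 5, 5) + np.tile(np.arange(5), n))
                cols.append(np.repeat(j * 5 + k, 5))
                vals.append(deriv.ravel())
        J = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(5 * n, 5 * n),
        )
        return J.tocsc()

    def _clip(self, u):
        u[0] = np.maximum(u[0], 0.0)
        u[1] = np.maximum(u[1], 0.0)
        u[2] = np.maximum(u[2], 0.0)
        u[3] = np.maximum(u[3], 0.0)
        u[4] = np.clip(u[4], math.log(1e-12), math.log(1e3))
        return u

    def newton(self, u, k_cat, tol, max_iter):
        res = self.residual(u, k_cat)
        norm = _rms(res)
        stalls = 0
        for _ in range(max_iter):
            if norm < tol:
                return u, norm
            J = self._fd_jacobian(u, res, k_cat)
            try:
                delta = splu(J).solve(-res.T.ravel())
            except RuntimeError as exc:  # singular factorization
                raise SolverError(f"linear solve failed: {exc}", norm) from exc
            delta = delta.reshape(self.n, 5).T
            # trust-region cap on the log-H+ step to avoid wild pH excursions
            dmax = np.max(np.abs(delta[4]))
            if dmax > 2.0:
                delta *= 2.0 / dmax
            lam, accepted = 1.0, False
            while lam >= 1.0 / 64.0:
                u_try = self._clip(u + lam * delta)
                res_try = self.residual(u_try, k_cat)
                norm_try = _rms(res_try)
                if norm_try < (1.0 - 1e-4 * lam) * norm or norm_try < tol:
                    u, res, norm = u_try, res_try, norm_try
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                u_try = self._clip(u + (1.0 / 64.0) * delta)
                res_try = self.residual(u_try, k_cat)
                u, res, norm = u_try, res_try, _rms(res_try)
                stalls += 1
                if stalls > 6:
                    raise SolverError(
                        f"Newton stalled at residual {norm:.3e}", norm
                    )
        if norm < tol:
            return u, norm
        raise SolverError(f"no convergence after {max_iter} iterations "
                          f"(residual {norm:.3e})", norm)


def _rms(res: np.ndarray) -> float:
    return float(np.sqrt(np.mean(res**2)))


def solve_steady_state(p: RDProblem) -> RadialProfile:
    """Solve the reduced system for one droplet radius.

    Initialization is the uniform far-field state; if the direct Newton solve
    fails (strongly reacting drops), the catalytic rate is ramped up in
    geometric continuation steps.
    """
    disc = _Discretization(p)
    u = disc.far_field_state()
    k_cat = p.kinetics.k_cat
    if k_cat == 0.0:
        res = disc.residual(u)
        return RadialProfile(disc.r, disc.species_of(u), _rms(res), p)
    try:
        u_sol, norm = disc.newton(u.copy(), k_cat, p.tol, p.max_newton)
    except SolverError:
        u_sol = u.copy()
        norm = math.inf
        for kc in np.geomspace(k_cat * 1e-3, k_cat, 8):
            u_sol, norm = disc.newton(u_sol, float(kc), p.tol, p.max_newton)
    profile = RadialProfile(disc.r, disc.species_of(u_sol), norm, p)
    if np.any(profile.c < -1e-12):
        raise SolverError("negative concentration in converged profile", norm)
    profile.c[profile.c < 0] = 0.0
    return profile


# ---------------------------------------------------------------------------
# diagnostics and the Damkohler analysis


def _combo_shell_flux(profile: RadialProfile, combo: str):
    """Shell flux 4 pi r^2 J(r) of one flux combination at face radii, mol/s."""
    if combo not in _COMBO_WEIGHTS:
        raise ValueError(f"unknown combination {combo!r}")
    disc = _Discretization(profile.problem)
    c = profile.c
    grad = (c[:, 1:] - c[:, :-1]) / np.diff(profile.r)
    F = -disc.D_face * grad
    J = sum(w * F[j] for j, w in _COMBO_WEIGHTS[combo].items())
    faces = 0.5 * (profile.r[:-1] + profile.r[1:])
    return faces, 4.0 * math.pi * faces**2 * J


def shell_flux(profile: RadialProfile, combo: str, r: float) -> float:
    """Total combined flux through the shell of radius ``r`` (mol/s)."""
    if not profile.r[0] <= r <= profile.r[-1]:
        raise ValueError(f"r={r:g} outside the solution grid")
    faces, flux = _combo_shell_flux(profile, combo)
    return float(np.interp(r, faces, flux))


def integrated_reaction_rate(profile: RadialProfile) -> float:
    """Volume-integrated Michaelis--Menten urea consumption, mol/s."""
    p = profile.problem
    S = smooth_step(profile.r, p.phases)
    rate = (
        p.kinetics.k_cat
        * p.kinetics.c_e_dense
        * S
        * profile.c[0]
        / (p.kinetics.K_m + profile.c[0])
    )
    return float(np.trapezoid(rate * 4.0 * math.pi * profile.r**2, profile.r))


def damkohler(
    kin: EnzymeKinetics,
    R: float,
    D1_dense: float,
) -> float:
    """Da = k_cat c_e^d R^2 / (D1 K_m), with the dense-phase urea diffusivity."""
    if R < 0 or D1_dense <= 0:
        raise ValueError("R must be non-negative and D1_dense positive")
    return kin.k_cat * kin.c_e_dense * R**2 / (D1_dense * kin.K_m)


def dense_phase_D1(p: RDProblem) -> float:
    return float(
        obstruction_diffusivity(
            p.species.D_w[0], p.phases.eta_dense, p.phases.eta_water
        )
    )


@dataclass
class DamkohlerSweepResult:
    """Radius sweep: droplet size against Da and the steady pH increase."""

    R: np.ndarray
    Da: np.ndarray
    dpH_center: np.ndarray
    dpH_edge: np.ndarray
    profiles: list = field(default_factory=list, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R_m": self.R,
                "Da": self.Da,
                "dpH_center": self.dpH_center,
                "dpH_edge": self.dpH_edge,
            }
        )


def sweep_radius(
    p: RDProblem, radii: Sequence[float], keep_profiles: bool = False
) -> DamkohlerSweepResult:
    """One converged solve per radius (ascending), tabulating Da and the
    center/edge pH increases over the far field."""
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be sorted ascending")
    pH_inf = -math.log10(assemble_unknowns(p.species.c_inf, p.equilibria)[4] / M_PER_M3)
    rows = {"R": [], "Da": [], "c": [], "e": []}
    profiles = []
    for R in radii:
        pr = p.with_radius(float(R))
        try:
            profile = solve_steady_state(pr)
        except SolverError as exc:
            raise SolverError(
                f"sweep failed at R={R:.3e} m: {exc}", exc.residual
            ) from exc
        rows["R"].append(R)
        rows["Da"].append(damkohler(p.kinetics, R, dense_phase_D1(pr)))
        rows["c"].append(profile.ph_center - pH_inf)
        rows["e"].append(profile.ph_at(R) - pH_inf)
        if keep_profiles:
            profiles.append(profile)
    return DamkohlerSweepResult(
        np.array(rows["R"]),
        np.array(rows["Da"]),
        np.array(rows["c"]),
        np.array(rows["e"]),
        profiles,
    )


@dataclass(frozen=True)
class ThresholdResult:
    Da_star: float | None
    bracketed: bool
    left_censored: bool = False


def threshold_da(sweep: DamkohlerSweepResult, dpH_cut: float = 0.1) -> ThresholdResult:
    """Interpolated Da at which the center pH increase first crosses the cut.

    Interpolation is linear in (log Da, dpH).  If the first sweep point
    already exceeds the cut the result is flagged left-censored; if no point
    does, the crossing is reported as not bracketed.
    """
    above = sweep.dpH_center > dpH_cut
    if not np.any(above):
        return ThresholdResult(None, bracketed=False)
    first = int(np.argmax(above))
    if first == 0:
        return ThresholdResult(float(sweep.Da[0]), bracketed=False, left_censored=True)
    d0, d1 = sweep.dpH_center[first - 1], sweep.dpH_center[first]
    l0, l1 = math.log(sweep.Da[first - 1]), math.log(sweep.Da[first])
    frac = (dpH_cut - d0) / (d1 - d0)
    return ThresholdResult(math.exp(l0 + frac * (l1 - l0)), bracketed=True)
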