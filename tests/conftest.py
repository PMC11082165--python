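import numpy as np
import pytest

from dialytaxis.reaction_network import (
    EnzymeKinetics,
    EquilibriumConstants,
    PhasePair,
    far_field_state,
)
from dialytaxis.rd_solver import RDProblem, solve_steady_state


@pytest.fixture(scope="session")
def eq():
    return EquilibriumConstants.from_pka()


@pytest.fixture(scope="session")
def reactor_problem(eq):
    """Urease micro-reactor at the reference operating point: pH_inf 6.8,
    100 mM urea and phosphate, 1 uM dense-phase enzyme, k_cat 4400/s,
    eta_dense 0.8 Pa s, R = 25 um."""
    species = far_field_state(6.8, 100.0, 100.0, eq)
    return RDProblem(
        species=species,
        equilibria=eq,
        kinetics=EnzymeKinetics(k_cat=4400.0, K_m=23.0, c_e_dense=1e-3),
        phases=PhasePair(eta_dense=0.8, eta_dilute=24e-3, R=25e-6),
    )


@pytest.fixture(scope="session")
def reactor_profile(reactor_problem):
    return solve_steady_state(reactor_problem)


@pytest.fixture(scope="session")
def uniform_source_problem(eq):
    """Uniform diffusivity in both phases and saturating substrate, so every
    conserved total obeys Laplace's equation with a uniform spherical source
    and the closed-form 1/r far field applies.  The large truncation radius
    keeps the infinite-domain form valid out to 10 R."""
    D_uniform = np.full(9, 1.0e-9)
    species = far_field_state(6.8, 100.0, 1e5, eq, D_w=D_uniform)
    return RDProblem(
        species=species,
        equilibria=eq,
        kinetics=EnzymeKinetics(k_cat=100.0, K_m=23.0, c_e_dense=1e-3),
        phases=PhasePair(eta_dense=1e-3, eta_dilute=1e-3, eta_water=1e-3, R=10e-6),
        domain_factor=5000.0,
        n_nodes=400,
        tol=1e-10,
    )
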