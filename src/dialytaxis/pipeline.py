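"""Configuration handling and end-to-end recipes.

Chains the stages -- synthetic data, estimators, the reaction--diffusion
solver and the Marangoni predictors -- into the two headline workflows:

* the observed-vs-predicted internal-speed construction (per-droplet
  Delta_gamma from a measured pH gradient against the 95th-percentile
  internal speed), run end to end on self-consistent synthetic data;
* the active-droplet report: per-radius steady-state solve, near-surface pH
  gradient, tension difference and predicted swimming speed.

Every run emits a provenance block (config hash, package version, seed) and
is a pure function of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    correct_and_convert,
    fit_ph_calibration,
    fit_ph_gradient,
    max_speed_p95,
)
from .motility import delta_gamma_across_drop, internal_speed_max
from .rd_solver import (
    RDProblem,
    damkohler,
    dense_phase_D1,
    solve_steady_state,
    sweep_radius,
    threshold_da,
)
from .reaction_network import (
    DEFAULT_D_WATER,
    EnzymeKinetics,
    EquilibriumConstants,
    PhasePair,
    far_field_state,
    parse_quantity,
)
from .synthetic_data import (
    SyntheticSpec,
    dye_ratio,
    gen_internal_flow_tracks,
    gen_ratiometric_field,
)

__all__ = [
    "load_params",
    "problem_from_config",
    "validate_config",
    "provenance",
    "run_speed_comparison_recipe",
    "run_active_droplet_recipe",
]

logger = logging.getLogger("dialytaxis")


def load_params(path=None) -> dict:
    """Load a chemistry/solver parameter file (the packaged defaults when
    ``path`` is None)."""
    if path is None:
        text = resources.files("dialytaxis").joinpath("data/default_params.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    validate_config(cfg, _PARAM_SCHEMA, "params")
    return cfg


_PARAM_SCHEMA = {
    "species": {"D_w": None},
    "equilibria": {"pKa2": None, "pKa3": None, "pKw": None, "pKa5": None},
    "kinetics": {"k_cat": None, "K_m": None, "c_e_dense": None},
    "phases": {
        "eta_dense": None,
        "eta_dilute": None,
        "eta_water": None,
        "R": None,
        "sharpness": None,
    },
    "far_field": {"pH_inf": None, "total_phosphate": None, "c_s": None},
    "solver": {"domain_factor": None, "n_nodes": None, "tol": None},
}


def validate_config(cfg: dict, schema: dict, where: str) -> None:
    """Reject unknown keys anywhere in the config tree."""
    for key, val in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown config key {where}.{key}")
        sub = schema[key]
        if isinstance(sub, dict) and sub and isinstance(val, dict):
            validate_config(val, sub, f"{where}.{key}")


def problem_from_config(cfg: dict, radius: float | None = None) -> RDProblem:
    """Build an :class:`RDProblem` from a parameter dict (see the packaged
    default file for the layout)."""
    eqc = cfg["equilibria"]
    eq = EquilibriumConstants.from_pka(
        pKa2=eqc["pKa2"], pKa3=eqc["pKa3"], pKw=eqc["pKw"], pKa5=eqc["pKa5"]
    )
    D_w = np.array(
        [parse_quantity(v) for v in cfg["species"]["D_w"].values()]
        if "species" in cfg
        else DEFAULT_D_WATER
    )
    ff = cfg["far_field"]
    species = far_field_state(
        pH_inf=float(ff["pH_inf"]),
        total_phosphate=parse_quantity(ff["total_phosphate"]),
        c_s=parse_quantity(ff["c_s"]),
        eq=eq,
        D_w=D_w,
    )
    kc = cfg["kinetics"]
    kin = EnzymeKinetics(
        k_cat=parse_quantity(kc["k_cat"]),
        K_m=parse_quantity(kc["K_m"]),
        c_e_dense=parse_quantity(kc["c_e_dense"]),
    )
    phc = cfg["phases"]
    phases = PhasePair(
        eta_dense=parse_quantity(phc["eta_dense"]),
        eta_dilute=parse_quantity(phc["eta_dilute"]),
        eta_water=parse_quantity(phc["eta_water"]),
        R=parse_quantity(phc["R"]) if radius is None else radius,
        sharpness=float(phc["sharpness"]),
    )
    sol = cfg.get("solver", {})
    return RDProblem(
        species=species,
        equilibria=eq,
        kinetics=kin,
        phases=phases,
        domain_factor=float(sol.get("domain_factor", 50)),
        n_nodes=int(sol.get("n_nodes", 260)),
        tol=float(sol.get("tol", 1e-8)),
    )


def provenance(config: dict, seed: int | None = None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": __version__,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# recipes


_SPEED_COMPARISON_DEFAULTS = {
    "seed": 0,
    "n_droplets": 30,
    "dgamma_dpH": -17e-6,  # N/m per pH unit (tension drops with pH)
    "eta_range": (0.1, 0.6),  # Pa s
    "radius_range": (15e-6, 40e-6),  # m
    "dpH_dx_range": (2e3, 8e3),  # pH per m
    "pH_background": 7.5,
    "imaging_noise": 0.01,
    "tracer_D": 8e-15,  # m^2/s, Brownian jitter of the velocimetry tracers
    "n_speed_tracers": 80,
    "n_speed_steps": 150,
}


def _measure_ph_gradient(R, pH0, grad, cal, noise, spec):
    """Image a linear pH profile around a dye-excluding droplet and fit the
    slope from 15 points outside each edge."""
    x = np.linspace(-4.0 * R, 4.0 * R, 161)
    ph_true = pH0 + grad * x
    inside = np.abs(x) < R
    i488, i405, vignette, _ = gen_ratiometric_field(
        ph_true,
        vignette_strength=0.25,
        dark_offset=100.0,
        noise=noise,
        droplet_mask=inside,
        spec=spec,
    )
    ph_meas, _ = correct_and_convert((i488, i405), vignette, 100.0, cal)
    fit = fit_ph_gradient(x, ph_meas, edges=(-R, R))
    return fit.slope


def _synthetic_calibration(noise: float, spec: SyntheticSpec):
    """Eight calibration solutions bracketing the pH range the profiles span.

    Each calibration point is a whole-image average, so its ratio noise is
    an order of magnitude below the per-pixel imaging noise.
    """
    rng = spec.rng()
    ph = np.linspace(6.8, 8.4, 8)
    ratio = dye_ratio(ph) * (1.0 + rng.normal(scale=0.1 * noise, size=ph.size))
    return fit_ph_calibration(np.column_stack([ph, ratio]))


def run_speed_comparison_recipe(config: dict | None = None):
    """Observed-vs-predicted internal speed over a synthetic droplet ensemble.

    Per droplet: a ground-truth pH gradient sets Delta_gamma and a matching
    internal circulation; the measurement chain (ratiometric imaging ->
    calibration -> edge-window slope -> Delta_gamma -> V_m prediction) is
    compared with the 95th-percentile speed of the velocimetry channel.
    Returns (table, summary) where summary carries the through-origin
    regression slope of observed on predicted speed and provenance.
    """
    cfg = dict(_SPEED_COMPARISON_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown speed-comparison config keys: {sorted(unknown)}")
        cfg.update(config)
    rng = np.random.default_rng(cfg["seed"])
    cal = _synthetic_calibration(
        cfg["imaging_noise"], SyntheticSpec(int(rng.integers(2**31)))
    )
    rows = []
    for i in range(cfg["n_droplets"]):
        R = rng.uniform(*cfg["radius_range"])
        eta = rng.uniform(*cfg["eta_range"])
        grad = rng.uniform(*cfg["dpH_dx_range"]) * rng.choice([-1.0, 1.0])
        dgam_true = delta_gamma_across_drop(R, cfg["dgamma_dpH"], grad)
        v_true = internal_speed_max(dgam_true, eta)

        slope = _measure_ph_gradient(
            R,
            cfg["pH_background"],
            grad,
            cal,
            cfg["imaging_noise"],
            SyntheticSpec(int(rng.integers(2**31))),
        )
        dgam_est = delta_gamma_across_drop(R, cfg["dgamma_dpH"], slope)
        v_pred = internal_speed_max(dgam_est, eta)

        _, speeds, _ = gen_internal_flow_tracks(
            V_m=v_true,
            R=R,
            D=cfg["tracer_D"],
            n=cfg["n_speed_tracers"],
            n_steps=cfg["n_speed_steps"],
            dt=min(0.5, R / max(v_true, 1e-12) / 10.0),
            spec=SyntheticSpec(int(rng.integers(2**31))),
        )
        v_obs = max_speed_p95(speeds)
        rows.append(
            {
                "droplet": i,
                "R_m": R,
                "eta_Pa_s": eta,
                "delta_gamma_N_per_m": dgam_est,
                "V_m_observed": v_obs,
                "V_m_predicted": v_pred,
            }
        )
    table = pd.DataFrame(rows)
    vp, vo = table["V_m_predicted"].to_numpy(), table["V_m_observed"].to_numpy()
    slope = float(np.dot(vo, vp) / np.dot(vp, vp))
    summary = {
        "regression_slope": slope,
        "n_droplets": len(rows),
        "provenance": provenance(cfg, cfg["seed"]),
    }
    logger.info("speed-comparison recipe: slope=%.3f over %d droplets", slope, len(rows))
    return table, summary


_ACTIVE_DEFAULTS = {
    "radii": tuple(np.geomspace(5e-6, 50e-6, 6)),
    "dgamma_dpH": -17e-6,  # N/m per pH unit
    "n_edge": 15,
}


def run_active_droplet_recipe(config: dict | None = None, params: dict | None = None):
    """Per-radius steady-state solve with the downstream speed prediction.

    For each droplet radius: solve the reaction--diffusion problem, fit the
    near-surface external pH slope (15 grid points outside the edge), form
    Delta_gamma = 2 R (dgamma/dpH)(dpH/dx) and the idealized-swimmer speed.
    Returns (table, dict of profiles keyed by radius, summary).
    """
    cfg = dict(_ACTIVE_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown active-droplet config keys: {sorted(unknown)}")
        cfg.update(config)
    params = params or load_params()
    rows, profiles = [], {}
    for R in cfg["radii"]:
        p = problem_from_config(params, radius=float(R))
        profile = solve_steady_state(p)
        fit = fit_ph_gradient(
            profile.r, profile.pH, edges=(-R, R), n_edge=cfg["n_edge"],
            sides=("right",),
        )
        dgam = delta_gamma_across_drop(R, cfg["dgamma_dpH"], fit.slope)
        eta = p.phases.eta_dense
        rows.append(
            {
                "R_m": R,
                "Da": damkohler(p.kinetics, R, dense_phase_D1(p)),
                "dpH_center": profile.ph_center - float(profile.pH[-1]),
                "dpH_dx_surface": fit.slope,
                "delta_gamma_N_per_m": dgam,
                "V_m_predicted": internal_speed_max(dgam, eta),
            }
        )
        profiles[float(R)] = profile
    table = pd.DataFrame(rows)
    summary = {"provenance": provenance({**cfg, "radii": list(map(float, cfg["radii"]))})}
    return table, profiles, summary
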