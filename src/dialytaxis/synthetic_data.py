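"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure of one measurement --
Brownian tracer tracks with background drift, internal-circulation
velocimetry, Stokes sedimentation, gravity-flattened drop contours, and
ratiometric dye images -- and echoes its ground-truth parameters into a
metadata dict.  Identical :class:`SyntheticSpec` (same seed, same
parameters) yields bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .estimators import DropContour, SedimentationObs, TrackSet, young_laplace_contour
from .motility import PhysicalConstants

__all__ = [
    "SyntheticSpec",
    "gen_brownian_tracks",
    "gen_internal_flow_tracks",
    "internal_flow_field",
    "gen_sedimentation",
    "gen_drop_contour",
    "dye_ratio",
    "gen_ratiometric_field",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Seed and name of one synthetic dataset; parameters are echoed into
    the generator's metadata for provenance."""

    seed: int
    name: str = ""
    params: dict = dc_field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_brownian_tracks(
    D: float,
    drift: tuple = (0.0, 0.0),
    n_tracks: int = 200,
    n_steps: int = 100,
    dt: float = 0.2,
    loc_noise: float = 0.0,
    spec: SyntheticSpec = SyntheticSpec(0),
):
    """Brownian tracks with constant background drift.

    Per-axis increments are independent Gaussians of variance 2 D dt plus
    drift*dt; optional additive localization noise perturbs every recorded
    position.  Returns (TrackSet, metadata).
    """
    if D < 0 or dt <= 0:
        raise ValueError("D must be non-negative and dt positive")
    rng = spec.rng()
    drift = np.asarray(drift, dtype=float)
    incr = rng.normal(
        loc=drift * dt,
        scale=math.sqrt(2.0 * D * dt),
        size=(n_tracks, n_steps, 2),
    )
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(incr, axis=1)], axis=1
    )
    if loc_noise > 0:
        pos = pos + rng.normal(scale=loc_noise, size=pos.shape)
    ts = TrackSet.from_arrays(list(pos), dt)
    meta = {
        "generator": "brownian_tracks",
        "seed": spec.seed,
        "D_true": D,
        "drift": tuple(drift),
        "dt": dt,
        "loc_noise": loc_noise,
    }
    return ts, meta


# ---------------------------------------------------------------------------
# internal circulation


def internal_flow_field(x, z, R: float):
    """Unit-amplitude internal Stokes-vortex velocity in a meridional plane.

    The classical closed-streamline circulation of a drop driven along z by
    an interfacial-tension gradient: u_x = x z / R^2,
    u_z = 1 - (2 x^2 + z^2) / R^2 inside r < R, zero outside.  The speed
    maxima (value 1) sit at the drop center and at the edge equator, and the
    radial velocity vanishes on r = R, so streamlines are confined.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    inside = x**2 + z**2 < R**2
    ux = np.where(inside, x * z / R**2, 0.0)
    uz = np.where(inside, 1.0 - (2 * x**2 + z**2) / R**2, 0.0)
    return ux, uz


# deterministic quadrature of the unit-field speed distribution (disk
# Fibonacci lattice), used to express the amplitude through the
# 95th-percentile speed -- the statistic the velocimetry reports.
def _unit_speed_quantile(R: float, q: float = 0.95, n: int = 40000) -> float:
    k = np.arange(n) + 0.5
    rad = R * np.sqrt(k / n)
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    ux, uz = internal_flow_field(rad * np.cos(theta), rad * np.sin(theta), R)
    return float(np.quantile(np.hypot(ux, uz), q))


def gen_internal_flow_tracks(
    V_m: float,
    R: float,
    D: float = 0.0,
    n: int = 150,
    dt: float = 0.1,
    n_steps: int = 150,
    spec: SyntheticSpec = SyntheticSpec(0),
):
    """Velocimetry data inside a circulating drop.

    ``V_m`` parameterizes the circulation strength as the 95th-percentile
    internal speed over the imaging plane (the statistic the measurement
    reports); the speed maxima sit at the drop center and edge.  Returns
    (TrackSet of advected tracers, per-step speed samples, metadata).
    Tracer advection uses Euler--Maruyama substeps capped at R/100
    displacement; speed samples are frame-to-frame displacements of
    particles redrawn uniformly over the drop each frame, emulating tracers
    entering and leaving the thin imaging slab.
    """
    if V_m < 0 or R <= 0 or D < 0 or dt <= 0:
        raise ValueError("V_m, D must be non-negative; R, dt positive")
    rng = spec.rng()
    amp = V_m / _unit_speed_quantile(R) if V_m > 0 else 0.0

    def velocity(p):
        ux, uz = internal_flow_field(p[:, 0], p[:, 1], R)
        return amp * np.column_stack([ux, uz])

    # long-lived tracers for the trajectory channel
    r0 = R * np.sqrt(rng.uniform(0.0, 0.96, n))
    th0 = rng.uniform(0.0, 2.0 * math.pi, n)
    p = np.column_stack([r0 * np.cos(th0), r0 * np.sin(th0)])
    n_sub = max(1, int(math.ceil((amp * dt) / (R / 100.0))))
    h = dt / n_sub
    positions = [p.copy()]
    for _ in range(n_steps):
        for _ in range(n_sub):
            p = p + velocity(p) * h
            if D > 0:
                p = p + rng.normal(scale=math.sqrt(2.0 * D * h), size=p.shape)
                # reflect jittered tracers back inside the drop
                rad = np.hypot(p[:, 0], p[:, 1])
                out = rad >= R
                if np.any(out):
                    p[out] *= ((2 * R - rad[out]) / rad[out])[:, None]
        positions.append(p.copy())
    tracks = np.stack(positions, axis=1)  # (n, n_steps+1, 2)
    ts = TrackSet.from_arrays(list(tracks), dt)

    # speed channel: virtual particles uniformly redrawn each frame
    m = n * n_steps
    rad = R * np.sqrt(rng.uniform(0.0, 1.0, m))
    th = rng.uniform(0.0, 2.0 * math.pi, m)
    q = np.column_stack([rad * np.cos(th), rad * np.sin(th)])
    disp = velocity(q) * dt
    if D > 0:
        disp = disp + rng.normal(scale=math.sqrt(2.0 * D * dt), size=disp.shape)
    speeds = np.hypot(disp[:, 0], disp[:, 1]) / dt
    meta = {
        "generator": "internal_flow_tracks",
        "seed": spec.seed,
        "V_m_true": V_m,
        "R": R,
        "D": D,
        "dt": dt,
        "amplitude": amp,
    }
    return ts, speeds, meta


def gen_sedimentation(
    delta_rho: float,
    eta_dilute: float = 24e-3,
    d_range: tuple = (20e-6, 200e-6),
    rel_noise: float = 0.1,
    n: int = 50,
    spec: SyntheticSpec = SyntheticSpec(0),
    consts: PhysicalConstants = PhysicalConstants(),
):
    """Terminal velocities of sedimenting drops with multiplicative noise:
    v = Delta_rho g d^2 / (18 eta) (1 + eps), eps ~ N(0, rel_noise)."""
    if eta_dilute <= 0 or n < 1:
        raise ValueError("eta_dilute must be positive and n >= 1")
    rng = spec.rng()
    d = rng.uniform(*d_range, n)
    v = delta_rho * consts.g * d**2 / (18.0 * eta_dilute)
    v = v * (1.0 + rng.normal(scale=rel_noise, size=n))
    obs = SedimentationObs(d=d, v_z=v)
    meta = {
        "generator": "sedimentation",
        "seed": spec.seed,
        "delta_rho_true": delta_rho,
        "eta_dilute": eta_dilute,
        "rel_noise": rel_noise,
    }
    return obs, meta


def gen_drop_contour(
    ell_c: float,
    apex_radius: float,
    n_points: int = 400,
    rel_noise: float = 0.0,
    arc_span: float = math.radians(160.0),
    spec: SyntheticSpec = SyntheticSpec(0),
):
    """Noisy two-sided silhouette of a sessile drop at known capillary length.

    The theoretical profile is mirrored about the apex axis and each point
    is displaced along the local outward normal by Gaussian noise of scale
    rel_noise * apex_radius.  The defaults reflect a millimetric non-wetting
    drop (contact angle near 180 degrees, so most of the profile is visible)
    imaged at a few micrometers per pixel: several hundred edge points per
    side spanning a 160-degree turning angle.
    """
    rng = spec.rng()
    half = young_laplace_contour(
        ell_c, apex_radius, arc_span=arc_span, n_points=n_points
    )
    x = np.concatenate([-half.x[::-1], half.x[1:]])
    z = np.concatenate([half.z[::-1], half.z[1:]])
    if rel_noise > 0:
        tx, tz = np.gradient(x), np.gradient(z)
        norm = np.hypot(tx, tz)
        nx, nz = tz / norm, -tx / norm
        amp = rng.normal(scale=rel_noise * apex_radius, size=x.size)
        x = x + amp * nx
        z = z + amp * nz
    contour = DropContour(x=x, z=z, contact_height=half.contact_height)
    meta = {
        "generator": "drop_contour",
        "seed": spec.seed,
        "ell_c_true": ell_c,
        "apex_radius_true": apex_radius,
        "rel_noise": rel_noise,
    }
    return contour, meta


# ---------------------------------------------------------------------------
# ratiometric dye imaging


def dye_ratio(ph, midpoint: float = 7.3, r_lo: float = 0.2, r_hi: float = 2.2):
    """Single-pKa sigmoidal dye response I488/I405 as a function of pH,
    monotone increasing with adjustable midpoint and dynamic range."""
    ph = np.asarray(ph, dtype=float)
    out = r_lo + (r_hi - r_lo) / (1.0 + 10.0 ** (midpoint - ph))
    return float(out) if out.ndim == 0 else out


def gen_ratiometric_field(
    ph_field: np.ndarray,
    vignette_strength: float = 0.3,
    dark_offset: float = 100.0,
    noise: float = 0.02,
    droplet_mask: np.ndarray | None = None,
    base_intensity: float = 2000.0,
    midpoint: float = 7.3,
    spec: SyntheticSpec = SyntheticSpec(0),
):
    """Raw (I488, I405) channels imaging a known pH field.

    The clean reference channel is uniform at ``base_intensity`` and the
    signal channel carries the sigmoidal dye ratio; both are multiplied by a
    parabolic vignette, offset by the sensor dark level, and perturbed by
    relative Gaussian noise.  Inside ``droplet_mask`` the dye is excluded,
    so both channels fall to the dark level there.  Returns
    (I488, I405, vignette, metadata).
    """
    ph_field = np.asarray(ph_field, dtype=float)
    rng = spec.rng()
    # parabolic flat-field falling off toward the image periphery
    axes = [np.linspace(-1.0, 1.0, s) for s in ph_field.shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    rho2 = sum(m**2 for m in mesh) / len(mesh)
    vignette = 1.0 - vignette_strength * rho2
    ratio = dye_ratio(ph_field, midpoint=midpoint)
    i405 = base_intensity * np.ones_like(ph_field)
    i488 = base_intensity * ratio
    if droplet_mask is not None:
        i405 = np.where(droplet_mask, 0.0, i405)
        i488 = np.where(droplet_mask, 0.0, i488)
    i405 = i405 * vignette + dark_offset
    i488 = i488 * vignette + dark_offset
    if noise > 0:
        i405 = i405 + rng.normal(scale=noise * base_intensity, size=i405.shape)
        i488 = i488 + rng.normal(scale=noise * base_intensity, size=i488.shape)
    meta = {
        "generator": "ratiometric_field",
        "seed": spec.seed,
        "vignette_strength": vignette_strength,
        "dark_offset": dark_offset,
        "noise": noise,
        "midpoint": midpoint,
        "base_intensity": base_intensity,
    }
    return i488, i405, vignette, meta
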