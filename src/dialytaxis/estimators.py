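"""Measurement-analysis estimators.

Turns raw observations into physical quantities:

* tracer diffusivity via the drift-insensitive covariance estimator, and
  viscosity via Stokes--Einstein;
* density difference from Stokes-regime sedimentation of small drops;
* capillary length from gravity-flattened sessile-drop contours
  (axisymmetric Young--Laplace shapes), and interfacial tension
  gamma = Delta_rho g ell_c^2 with propagated uncertainty;
* ratiometric-dye pH calibration (cubic inverse map), image correction, and
  pH-gradient extraction around droplet edges;
* the 95th-percentile internal-speed statistic and absorbance-based
  concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .motility import PhysicalConstants

__all__ = [
    "TrackSet",
    "DiffusivityEstimate",
    "cve_diffusivity",
    "msd_diffusivity",
    "ViscosityEstimate",
    "stokes_einstein_viscosity",
    "SedimentationObs",
    "SedimentationFit",
    "fit_sedimentation",
    "DropContour",
    "young_laplace_contour",
    "ContourFit",
    "fit_contour",
    "TensionEstimate",
    "gamma_from_capillary",
    "CalibrationCurve",
    "fit_ph_calibration",
    "correct_and_convert",
    "GradientFit",
    "fit_ph_gradient",
    "width_averaged_profile",
    "max_speed_p95",
    "concentration_from_absorbance",
]


# ---------------------------------------------------------------------------
# particle tracks and microrheology


@dataclass
class TrackSet:
    """Uniformly sampled 2-D particle trajectories.

    Stored as a long-format table (track_id, t_s, x_m, y_m) with a common
    frame interval ``dt``.
    """

    data: pd.DataFrame
    dt: float

    def __post_init__(self) -> None:
        required = {"track_id", "t_s", "x_m", "y_m"}
        if not required <= set(self.data.columns):
            raise ValueError(f"track table must have columns {sorted(required)}")
        if self.dt <= 0:
            raise ValueError("frame interval must be positive")
        for tid, g in self.data.groupby("track_id"):
            dts = np.diff(g["t_s"].to_numpy())
            if len(g) < 2:
                raise ValueError(f"track {tid} has fewer than 2 points")
            if np.any(dts <= 0) or not np.allclose(dts, self.dt, rtol=1e-6):
                raise ValueError(f"track {tid} is not uniformly sampled at dt")

    @classmethod
    def from_arrays(cls, tracks: Iterable[np.ndarray], dt: float) -> "TrackSet":
        """Build from per-track (n_i, 2) position arrays sampled at ``dt``."""
        frames = []
        for tid, xy in enumerate(tracks):
            xy = np.asarray(xy, dtype=float)
            frames.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "t_s": dt * np.arange(len(xy)),
                        "x_m": xy[:, 0],
                        "y_m": xy[:, 1],
                    }
                )
            )
        return cls(pd.concat(frames, ignore_index=True), dt)

    def displacements(self, min_points: int = 2):
        """Per-track per-axis frame-to-frame displacement arrays."""
        out = []
        for _, g in self.data.groupby("track_id"):
            if len(g) < min_points:
                continue
            out.append(np.diff(g["x_m"].to_numpy()))
            out.append(np.diff(g["y_m"].to_numpy()))
        return out

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TrackSet":
        df = pd.read_csv(path)
        dts = df.groupby("track_id")["t_s"].diff().dropna()
        return cls(df, float(dts.median()))


@dataclass(frozen=True)
class DiffusivityEstimate:
    D: float  # m^2/s
    se: float  # standard error, m^2/s
    n_tracks: int
    n_excluded: int
    negative: bool = False


def _cve_terms(d: np.ndarray):
    """(sum, count) triples of the three displacement moments of one axis."""
    return (
        (d**2).sum(), d.size,
        (d[:-1] * d[1:]).sum(), d.size - 1,
        (d[2:] * d[:-2]).sum(), d.size - 2,
    )


def cve_diffusivity(ts: TrackSet, pooling: str = "pooled") -> DiffusivityEstimate:
    """Drift-insensitive covariance-based diffusivity estimator.

    D = <dx^2>/(2 dt) + <dx_n dx_{n+1}>/dt - (3/2) <dx_{n+1} dx_{n-1}>/dt,
    the averages pooled over all tracks, all time points and both axes.  The
    combination cancels both a constant drift and static localization noise;
    the estimate may come out slightly negative in noise and is returned
    as-is with a flag.  ``pooling='per_track'`` instead averages per-track
    estimates (differs at unequal track lengths).
    """
    if pooling not in ("pooled", "per_track"):
        raise ValueError("pooling must be 'pooled' or 'per_track'")
    dt = ts.dt
    per_axis = [d for d in ts.displacements() if d.size >= 3]
    n_excluded = ts.n_tracks - len(per_axis) // 2
    if not per_axis:
        raise ValueError("no track has the 4 points needed for the estimator")

    def estimate(groups):
        s1 = n1 = s2 = n2 = s3 = n3 = 0.0
        for d in groups:
            a, b, c, e, f, g = _cve_terms(d)
            s1 += a; n1 += b; s2 += c; n2 += e; s3 += f; n3 += g
        return s1 / n1 / (2 * dt) + s2 / n2 / dt - 1.5 * s3 / n3 / dt

    per_track = [
        estimate(per_axis[i : i + 2]) for i in range(0, len(per_axis), 2)
    ]
    if pooling == "pooled":
        D = estimate(per_axis)
    else:
        D = float(np.mean(per_track))
    se = (
        float(np.std(per_track, ddof=1) / math.sqrt(len(per_track)))
        if len(per_track) > 1
        else math.nan
    )
    return DiffusivityEstimate(
        D=float(D),
        se=se,
        n_tracks=len(per_track),
        n_excluded=n_excluded,
        negative=D < 0,
    )


def msd_diffusivity(ts: TrackSet, correct_drift: bool = False) -> float:
    """Naive lag-1 MSD estimator <dx^2>/(2 dt), optionally after removing the
    global mean displacement per frame (the constant-background-flow model).

    Without correction a constant drift v biases this estimator upward by
    v^2 dt / 2 per axis; it is provided as the cross-check diagnostic for
    :func:`cve_diffusivity`, not as the primary estimator.
    """
    per_axis = ts.displacements()
    if correct_drift:
        means = [np.mean(np.concatenate(per_axis[i::2])) for i in (0, 1)]
        per_axis = [d - means[i % 2] for i, d in enumerate(per_axis)]
    d_all = np.concatenate(per_axis)
    return float(np.mean(d_all**2) / (2 * ts.dt))


@dataclass(frozen=True)
class ViscosityEstimate:
    eta: float  # Pa s
    d_eta: float


def stokes_einstein_viscosity(
    D: float,
    a: float = 0.1e-6,
    consts: PhysicalConstants = PhysicalConstants(),
    rel_uncertainty: float = 0.2,
) -> ViscosityEstimate:
    """eta = kT / (6 pi a D) for a tracer of radius ``a``.

    The relative uncertainty of D propagates directly: d_eta/eta = dD/D
    (20% by measurement convention).
    """
    if D <= 0:
        raise ValueError("non-physical diffusivity: D must be positive")
    if a <= 0:
        raise ValueError("tracer radius must be positive")
    eta = consts.kT / (6.0 * math.pi * a * D)
    return ViscosityEstimate(eta=eta, d_eta=rel_uncertainty * eta)


# ---------------------------------------------------------------------------
# sedimentation


@dataclass
class SedimentationObs:
    """Terminal-velocity observations of sedimenting drops."""

    d: np.ndarray  # diameters, m
    v_z: np.ndarray  # terminal velocities, m/s

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.v_z = np.asarray(self.v_z, dtype=float)
        if self.d.shape != self.v_z.shape:
            raise ValueError("d and v_z must have matching shapes")
        if np.any(self.d <= 0) or not np.all(np.isfinite(self.v_z)):
            raise ValueError("diameters must be positive and velocities finite")


@dataclass(frozen=True)
class SedimentationFit:
    delta_rho: float  # kg/m^3
    d_delta_rho: float
    A: float  # fitted v = A d^2 coefficient, 1/(m s)
    sign_ok: bool  # False when the fitted density difference is negative


def fit_sedimentation(
    obs: SedimentationObs,
    eta_dilute: float,
    consts: PhysicalConstants = PhysicalConstants(),
) -> SedimentationFit:
    """Least-squares v_z = A d^2 through the origin; Delta_rho = 18 eta A / g.

    Valid in the Stokes regime for drops much more viscous than the
    surrounding dilute phase (rigid-sphere drag).
    """
    if obs.d.size < 3:
        raise ValueError("need at least 3 observations")
    if obs.d.max() / obs.d.min() < 2.0:
        raise ValueError("observations must span at least a factor 2 in diameter")
    x = obs.d**2
    A = float(np.dot(x, obs.v_z) / np.dot(x, x))
    resid = obs.v_z - A * x
    var_A = float(resid @ resid) / max(obs.d.size - 1, 1) / float(x @ x)
    scale = 18.0 * eta_dilute / consts.g
    return SedimentationFit(
        delta_rho=scale * A,
        d_delta_rho=scale * math.sqrt(var_A),
        A=A,
        sign_ok=A >= 0,
    )


# ---------------------------------------------------------------------------
# sessile-drop shapes and interfacial tension


@dataclass
class DropContour:
    """Silhouette of an axisymmetric sessile drop.

    ``x`` is the horizontal coordinate (both sides of the apex axis allowed),
    ``z`` the depth below the apex (increasing downward).
    """

    x: np.ndarray  # m
    z: np.ndarray  # m
    contact_height: float = math.nan  # z of the contact plane

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must have the same shape")


def _yl_profile(ell_c: float, apex_radius: float, arc_span: float,
                n_points: int = 400, rtol: float = 1e-10):
    """Integrate the axisymmetric capillary-statics profile from the apex.

    Arc-length form of the Young--Laplace balance: the mean curvature grows
    linearly with depth, phi' + sin(phi)/x = 2/b + z/ell_c^2.  Returns
    (x, z, phi) sampled along the arc up to turning angle ``arc_span``.
    """
    b = apex_radius

    def rhs(s, y):
        x, z, phi = y
        if x < 1e-12 * b:
            dphi = 1.0 / b  # apex limit: sin(phi)/x -> phi'
        else:
            dphi = 2.0 / b + z / ell_c**2 - math.sin(phi) / x
        return [math.cos(phi), math.sin(phi), dphi]

    def reached(s, y):
        return y[2] - arc_span

    reached.terminal = True
    reached.direction = 1.0
    # generous arc-length budget: flattened drops have long equators
    s_max = (arc_span + 1.0) * max(b, ell_c**2 / b) * 4.0
    sol = solve_ivp(
        rhs,
        (0.0, s_max),
        [0.0, 0.0, 0.0],
        events=reached,
        max_step=min(s_max / (2 * n_points), arc_span * b / 100.0),
        dense_output=True,
        rtol=rtol,
        atol=1e-14 * max(b, 1e-6),
    )
    if not sol.success or sol.t_events[0].size == 0:
        raise RuntimeError(
            f"contour integration failed (ell_c={ell_c:g}, apex_radius={b:g})"
        )
    s = np.linspace(0.0, sol.t_events[0][0], n_points)
    x, z, phi = sol.sol(s)
    return x, z, phi


def young_laplace_contour(
    ell_c: float,
    apex_radius: float,
    arc_span: float = math.radians(150.0),
    n_points: int = 200,
) -> DropContour:
    """Theoretical sessile-drop silhouette at given capillary length.

    ``arc_span`` is the interface turning angle at which the contour stops
    (pi corresponds to a 180-degree contact angle).  As ell_c -> infinity
    the shape reduces to a spherical cap of radius ``apex_radius``; for
    apex_radius >> ell_c gravity flattens the drop.
    """
    if ell_c <= 0 or apex_radius <= 0 or not 0 < arc_span <= math.pi:
        raise ValueError("ell_c, apex_radius must be positive; arc_span in (0, pi]")
    x, z, _ = _yl_profile(ell_c, apex_radius, arc_span, n_points)
    return DropContour(x=x, z=z, contact_height=float(z[-1]))


@dataclass(frozen=True)
class ContourFit:
    ell_c: float
    d_ell_c: float
    apex_radius: float
    x0: float
    z0: float
    tilt: float
    rms: float  # residual distance RMS, m


def fit_contour(c: DropContour, d_ell_c_convention: float = 0.1) -> ContourFit:
    """Nonlinear least-squares Young--Laplace fit of a measured contour.

    Free parameters: capillary length, apex radius, apex position and a
    small tilt of the symmetry axis.  The reported uncertainty is the 10%
    measurement convention unless the fit covariance is larger.
    """
    if c.x.size < 30:
        raise ValueError("need at least 30 contour points")
    xs, zs = c.x, c.z
    # initial pose: apex at the topmost point, mid-span axis
    z0_init = float(zs.min())
    x0_init = float(0.5 * (xs.min() + xs.max()))
    width = float(xs.max() - xs.min())
    height = float(zs.max() - z0_init)
    b_init = max(0.5 * width, 1e-9)
    ell_init = max(height, 0.25 * width)
    scale = max(width, height)

    def residuals(theta):
        log_ell, log_b, x0, z0, tilt = theta
        try:
            px, pz, _ = _yl_profile(
                math.exp(log_ell), math.exp(log_b), math.radians(165.0),
                n_points=250, rtol=1e-8,
            )
        except RuntimeError:
            return np.full(xs.size, 10.0)
        # fold data into the canonical half-plane frame of the profile
        ct, st = math.cos(tilt), math.sin(tilt)
        u = ct * (xs - x0) + st * (zs - z0)
        w = -st * (xs - x0) + ct * (zs - z0)
        pts = np.column_stack([np.abs(u), w])
        verts = np.column_stack([px, pz])
        tree = cKDTree(verts)
        _, idx = tree.query(pts)
        # exact distance to the polyline segments adjacent to the nearest
        # vertex (nearest-vertex distance alone biases the fit)
        dist = np.full(pts.shape[0], np.inf)
        for lo in (np.maximum(idx - 1, 0), np.minimum(idx, len(verts) - 2)):
            a = verts[lo]
            ab = verts[lo + 1] - a
            t = np.clip(
                np.einsum("ij,ij->i", pts - a, ab)
                / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300),
                0.0,
                1.0,
            )
            d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
            dist = np.minimum(dist, d)
        return dist / scale

    theta0 = [math.log(ell_init), math.log(b_init), x0_init, z0_init, 0.0]
    fit = least_squares(
        residuals,
        theta0,
        x_scale=[0.3, 0.3, 0.1 * scale, 0.1 * scale, 0.05],
        xtol=1e-12,
        ftol=1e-12,
    )
    if not fit.success:
        raise RuntimeError(f"contour fit did not converge: {fit.message}")
    ell_c = math.exp(fit.x[0])
    # covariance of log ell_c from the Gauss-Newton approximation
    m = fit.fun.size - fit.x.size
    rms = float(np.sqrt(np.mean(fit.fun**2))) * scale
    try:
        cov = np.linalg.inv(fit.jac.T @ fit.jac) * (
            2 * fit.cost / max(m, 1)
        )
        d_log_ell = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        d_log_ell = 0.0
    d_ell = max(d_ell_c_convention, d_log_ell) * ell_c
    return ContourFit(
        ell_c=ell_c,
        d_ell_c=d_ell,
        apex_radius=math.exp(fit.x[1]),
        x0=fit.x[2],
        z0=fit.x[3],
        tilt=fit.x[4],
        rms=rms,
    )


@dataclass(frozen=True)
class TensionEstimate:
    """Capillary length, density difference and the derived tension."""

    ell_c: float  # m
    d_ell_c: float
    delta_rho: float  # kg/m^3
    d_delta_rho: float
    gamma: float  # N/m
    d_gamma: float


def gamma_from_capillary(
    ell_c: float,
    d_ell_c: float,
    delta_rho: float,
    d_delta_rho: float,
    consts: PhysicalConstants = PhysicalConstants(),
) -> TensionEstimate:
    """gamma = Delta_rho g ell_c^2 with
    (d_gamma/gamma)^2 = (d_Delta_rho/Delta_rho)^2 + 2 (d_ell_c/ell_c)^2."""
    if ell_c <= 0 or delta_rho <= 0:
        raise ValueError("ell_c and delta_rho must be positive")
    gamma = delta_rho * consts.g * ell_c**2
    rel = math.sqrt((d_delta_rho / delta_rho) ** 2 + 2.0 * (d_ell_c / ell_c) ** 2)
    return TensionEstimate(
        ell_c=ell_c,
        d_ell_c=d_ell_c,
        delta_rho=delta_rho,
        d_delta_rho=d_delta_rho,
        gamma=gamma,
        d_gamma=rel * gamma,
    )


# ---------------------------------------------------------------------------
# ratiometric pH imaging


@dataclass
class CalibrationCurve:
    """Cubic inverse map pH = f^-1(I488/I405) fitted to calibration solutions."""

    coeffs: np.ndarray  # cubic coefficients, highest power first (np.polyval)
    ratio_range: tuple  # validity interval of the ratio
    rms: float  # fit residual RMS, pH units
    monotone: bool = True

    def ph_from_ratio(self, ratio):
        """Apply the calibration; points outside the calibrated ratio range
        are still evaluated but reported in the returned mask."""
        ratio = np.asarray(ratio, dtype=float)
        ph = np.polyval(self.coeffs, ratio)
        out_of_range = (ratio < self.ratio_range[0]) | (ratio > self.ratio_range[1])
        return ph, out_of_range


def fit_ph_calibration(points: Sequence) -> CalibrationCurve:
    """Least-squares cubic pH(ratio) through (pH_i, ratio_i) pairs.

    A non-monotone ratio sequence (in pH order) only warns -- the cubic fit
    still proceeds -- because single swapped neighbours are common at the
    flat ends of the dye response.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (pH, ratio) pairs")
    ph, ratio = pts[np.argsort(pts[:, 0])].T
    monotone = bool(np.all(np.diff(ratio) > 0) or np.all(np.diff(ratio) < 0))
    if not monotone:
        warnings.warn("ratio is not monotone in pH over the calibration range")
    coeffs = np.polyfit(ratio, ph, 3)
    rms = float(np.sqrt(np.mean((np.polyval(coeffs, ratio) - ph) ** 2)))
    return CalibrationCurve(
        coeffs=coeffs,
        ratio_range=(float(ratio.min()), float(ratio.max())),
        rms=rms,
        monotone=monotone,
    )


def correct_and_convert(
    intensities: tuple,
    vignette_field: np.ndarray,
    dark_offset: float,
    cal: CalibrationCurve,
):
    """Convert raw (I488, I405) images to pH.

    The sensor dark level is subtracted, both channels are flat-field divided
    by the vignette, and the ratio is pushed through the calibration.
    Returns (pH array, mask) where masked points had a non-positive
    denominator after dark subtraction (e.g. dye-free droplet interiors) or
    fell outside the calibrated ratio range.
    """
    i488, i405 = (np.asarray(a, dtype=float) for a in intensities)
    vignette = np.asarray(vignette_field, dtype=float)
    if i488.shape != i405.shape or i488.shape != vignette.shape:
        raise ValueError("intensity and vignette fields must share a shape")
    if np.any(vignette <= 0):
        raise ValueError("vignette field must be strictly positive")
    num = (i488 - dark_offset) / vignette
    den = (i405 - dark_offset) / vignette
    bad = den <= 0
    ratio = np.where(bad, 1.0, num / np.where(bad, 1.0, den))
    ph, out_of_range = cal.ph_from_ratio(ratio)
    mask = bad | out_of_range
    ph = np.where(mask, np.nan, ph)
    return ph, mask


def width_averaged_profile(ph_map: np.ndarray, axis: int = 0) -> np.ndarray:
    """Average a 2-D pH map across the image width (ignoring masked pixels),
    the chamber-mode reduction applied before the line fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(ph_map, axis=axis)


@dataclass(frozen=True)
class GradientFit:
    slope: float  # pH per m
    se: float
    intercept: float
    n_points: int


def fit_ph_gradient(
    x: np.ndarray,
    ph: np.ndarray,
    edges: tuple,
    n_edge: int = 15,
    sides: tuple = ("left", "right"),
) -> GradientFit:
    """Slope of pH across a droplet from points just outside its edges.

    The ``n_edge`` valid samples nearest each requested edge (outside the
    drop, where the dye reports pH) enter a single straight-line fit.
    """
    x = np.asarray(x, dtype=float)
    ph = np.asarray(ph, dtype=float)
    valid = np.isfinite(ph)
    sel = np.zeros_like(valid)
    for side in sides:
        if side == "left":
            cand = np.flatnonzero(valid & (x < edges[0]))
        elif side == "right":
            cand = np.flatnonzero(valid & (x > edges[1]))
        else:
            raise ValueError(f"unknown side {side!r}")
        if cand.size < n_edge:
            raise ValueError(
                f"only {cand.size} valid points on the {side} side "
                f"(need {n_edge})"
            )
        edge = edges[0] if side == "left" else edges[1]
        nearest = cand[np.argsort(np.abs(x[cand] - edge))[:n_edge]]
        sel[nearest] = True
    xw, pw = x[sel], ph[sel]
    (slope, intercept), cov = np.polyfit(xw, pw, 1, cov=True)
    return GradientFit(
        slope=float(slope),
        se=float(math.sqrt(max(cov[0, 0], 0.0))),
        intercept=float(intercept),
        n_points=int(sel.sum()),
    )


# ---------------------------------------------------------------------------
# velocimetry statistic and absorbance


def max_speed_p95(speeds: np.ndarray) -> float:
    """Maximum internal speed defined as the 95th percentile of |V|.

    The empirical CDF is interpolated linearly; the top 5% of recorded
    speeds (likely tracking noise) never affect the statistic.
    """
    speeds = np.abs(np.asarray(speeds, dtype=float))
    if speeds.size < 20:
        raise ValueError("need at least 20 speed samples")
    return float(np.quantile(speeds, 0.95))


def concentration_from_absorbance(
    absorbances: Sequence[float],
    dilutions: Sequence[float],
    epsilon: float,
    path: float = 1.0,
) -> float:
    """Mean concentration (mM) from replicate dilutions via Beer--Lambert.

    ``epsilon`` in mM^-1 cm^-1 and ``path`` in cm; each sample contributes
    A / (epsilon * path) * dilution, negative absorbances are excluded with
    a warning.
    """
    A = np.asarray(absorbances, dtype=float)
    dil = np.asarray(dilutions, dtype=float)
    if A.shape != dil.shape:
        raise ValueError("absorbances and dilutions must have equal length")
    if path <= 0 or epsilon <= 0:
        raise ValueError("epsilon and path must be positive")
    keep = A >= 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} negative absorbance(s)")
    if not np.any(keep):
        raise ValueError("no usable absorbance values")
    return float(np.mean(A[keep] / (epsilon * path) * dil[keep]))
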