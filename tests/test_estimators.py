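import math

import numpy as np
import pytest

from dialytaxis.estimators import (
    CalibrationCurve,
    DropContour,
    SedimentationObs,
    TrackSet,
    concentration_from_absorbance,
    correct_and_convert,
    cve_diffusivity,
    fit_contour,
    fit_ph_calibration,
    fit_ph_gradient,
    fit_sedimentation,
    gamma_from_capillary,
    max_speed_p95,
    msd_diffusivity,
    stokes_einstein_viscosity,
    width_averaged_profile,
    young_laplace_contour,
)
from dialytaxis.motility import PhysicalConstants
from dialytaxis.synthetic_data import (
    SyntheticSpec,
    dye_ratio,
    gen_brownian_tracks,
    gen_drop_contour,
    gen_ratiometric_field,
    gen_sedimentation,
)


class TestCVEDiffusivity:
    def test_pure_drift_cancels_exactly(self):
        """Straight-line tracks (constant velocity, no noise): the three
        moment terms cancel algebraically, 1/2 + 1 - 3/2 = 0."""
        v = np.array([0.7e-6, -0.3e-6])
        t = np.arange(50)[:, None] * 0.2
        ts = TrackSet.from_arrays([v * t for _ in range(5)], dt=0.2)
        est = cve_diffusivity(ts)
        assert abs(est.D) < 1e-22  # femtoscale cancellation residue

    @pytest.mark.parametrize("drift", [(0.0, 0.0), (4e-8, -2e-8)])
    def test_recovers_diffusivity_within_3se(self, drift):
        D_true = 2.2e-15
        ts, _ = gen_brownian_tracks(
            D=D_true, drift=drift, n_tracks=200, n_steps=100, dt=0.2,
            spec=SyntheticSpec(11),
        )
        est = cve_diffusivity(ts)
        assert abs(est.D - D_true) < 3 * est.se

    def test_unbiased_under_localization_noise(self):
        """Static localization noise inflates the lag-0 term but the lag-1
        covariance compensates; the naive MSD estimator does not."""
        D_true = 2.2e-15
        dt = 0.2
        sigma = math.sqrt(D_true * dt)  # sizeable static noise
        ts, _ = gen_brownian_tracks(
            D=D_true, n_tracks=300, n_steps=100, dt=dt, loc_noise=sigma,
            spec=SyntheticSpec(12),
        )
        est = cve_diffusivity(ts)
        assert abs(est.D - D_true) < 3 * est.se
        naive = msd_diffusivity(ts)
        assert naive - D_true > 5 * est.se  # biased up by sigma^2/dt

    def test_drift_biases_msd_but_not_cve(self):
        D_true = 1.0e-15
        dt, v = 0.5, 8e-8
        ts, _ = gen_brownian_tracks(
            D=D_true, drift=(v, 0.0), n_tracks=200, n_steps=100, dt=dt,
            spec=SyntheticSpec(13),
        )
        naive = msd_diffusivity(ts)
        est = cve_diffusivity(ts)
        # the per-axis drift bias v^2 dt / 2 is halved by pooling both axes
        assert naive - D_true == pytest.approx(v**2 * dt / 4, rel=0.25)
        assert abs(est.D - D_true) < 3 * est.se
        corrected = msd_diffusivity(ts, correct_drift=True)
        assert abs(corrected - D_true) < 5 * est.se

    def test_short_tracks_excluded(self):
        good = np.cumsum(np.ones((10, 2)), axis=0) * 1e-7
        short = good[:3]
        ts = TrackSet.from_arrays([good, short, good], dt=0.1)
        est = cve_diffusivity(ts)
        assert est.n_tracks == 2 and est.n_excluded == 1

    def test_all_tracks_too_short_errors(self):
        ts = TrackSet.from_arrays([np.zeros((3, 2)), np.zeros((2, 2))], dt=0.1)
        with pytest.raises(ValueError, match="4 points"):
            cve_diffusivity(ts)

    def test_permutation_invariant(self):
        ts, _ = gen_brownian_tracks(D=1e-15, n_tracks=20, n_steps=30,
                                    spec=SyntheticSpec(14))
        shuffled = TrackSet(
            ts.data.sort_values(["track_id", "t_s"], ascending=[False, True])
            .reset_index(drop=True),
            ts.dt,
        )
        assert cve_diffusivity(shuffled).D == pytest.approx(cve_diffusivity(ts).D)


class TestStokesEinstein:
    def test_unit_viscosity_anchor(self):
        # a = 0.1 um tracer: D = 2.18e-15 m2/s corresponds to ~1 Pa s at 25 C
        est = stokes_einstein_viscosity(2.18e-15, a=0.1e-6)
        assert est.eta == pytest.approx(1.0, abs=0.01)
        assert est.d_eta == pytest.approx(0.2 * est.eta)

    def test_inverse_proportionality(self):
        assert stokes_einstein_viscosity(1e-15).eta == pytest.approx(
            2 * stokes_einstein_viscosity(2e-15).eta
        )

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            stokes_einstein_viscosity(-1e-16)


class TestSedimentation:
    def test_noiseless_exact_recovery(self):
        consts = PhysicalConstants()
        d = np.linspace(20e-6, 200e-6, 10)
        v = 50.0 * consts.g * d**2 / (18 * 24e-3)
        fit = fit_sedimentation(SedimentationObs(d, v), 24e-3)
        assert fit.delta_rho == pytest.approx(50.0, rel=1e-12)
        assert fit.sign_ok

    def test_forward_velocity_value(self):
        # 50 kg/m^3 drop of 100 um diameter in 24 mPa s: ~11.35 um/s
        v = 50.0 * 9.81 * (100e-6) ** 2 / (18 * 24e-3)
        assert v == pytest.approx(11.35e-6, abs=0.01e-6)

    def test_zero_velocities_give_zero_density(self):
        d = np.linspace(20e-6, 100e-6, 5)
        fit = fit_sedimentation(SedimentationObs(d, np.zeros(5)), 24e-3)
        assert fit.delta_rho == 0.0

    def test_noisy_recovery_within_3se(self):
        obs, meta = gen_sedimentation(50.0, rel_noise=0.1, n=50,
                                      spec=SyntheticSpec(21))
        fit = fit_sedimentation(obs, meta["eta_dilute"])
        assert abs(fit.delta_rho - 50.0) < 3 * fit.d_delta_rho

    def test_negative_fit_flagged(self):
        d = np.linspace(20e-6, 100e-6, 5)
        fit = fit_sedimentation(SedimentationObs(d, -1e-6 * np.ones(5)), 24e-3)
        assert not fit.sign_ok

    def test_span_requirement(self):
        d = np.full(5, 50e-6)
        with pytest.raises(ValueError, match="span"):
            fit_sedimentation(SedimentationObs(d, np.ones(5)), 24e-3)


class TestYoungLaplace:
    def test_zero_bond_limit_is_spherical(self):
        b = 1e-3
        c = young_laplace_contour(ell_c=1e4 * b, apex_radius=b)
        radius_dev = np.hypot(c.x, c.z - b) - b
        assert np.abs(radius_dev).max() < 1e-6 * b

    def test_gravity_flattens_large_drops(self):
        # apex radius >> capillary length: height well below a hemisphere's
        c = young_laplace_contour(ell_c=0.5e-3, apex_radius=3e-3,
                                  arc_span=math.pi / 2)
        width = 2 * c.x.max()
        height = c.z.max()
        assert height / width < 0.3

    def test_noiseless_round_trip(self):
        contour, meta = gen_drop_contour(0.5e-3, 1.0e-3, rel_noise=0.0,
                                         spec=SyntheticSpec(31))
        fit = fit_contour(contour)
        assert fit.ell_c == pytest.approx(meta["ell_c_true"], rel=1e-3)
        assert fit.apex_radius == pytest.approx(meta["apex_radius_true"], rel=1e-3)

    def test_one_percent_noise_round_trip(self):
        contour, meta = gen_drop_contour(0.5e-3, 1.0e-3, rel_noise=0.01,
                                         spec=SyntheticSpec(32))
        fit = fit_contour(contour)
        assert fit.ell_c == pytest.approx(meta["ell_c_true"], rel=0.01)
        assert fit.d_ell_c >= 0.1 * fit.ell_c  # the 10% convention floor

    def test_fit_is_unbiased_over_seeds(self):
        errors = []
        for seed in range(40):
            contour, meta = gen_drop_contour(0.5e-3, 1.0e-3, rel_noise=0.01,
                                             spec=SyntheticSpec(100 + seed))
            fit = fit_contour(contour)
            errors.append(fit.ell_c / meta["ell_c_true"] - 1.0)
        assert abs(np.mean(errors)) < 0.003

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="30"):
            fit_contour(DropContour(np.zeros(10), np.zeros(10)))


class TestTension:
    def test_known_value(self):
        est = gamma_from_capillary(0.5e-3, 0.0, 50.0, 0.0)
        assert est.gamma == pytest.approx(1.23e-4, abs=0.01e-4)
        assert est.d_gamma == 0.0

    def test_identity_holds_exactly(self):
        est = gamma_from_capillary(0.37e-3, 0.037e-3, 62.0, 5.0)
        assert est.gamma == est.delta_rho * 9.81 * est.ell_c**2

    def test_error_propagation_formula(self):
        est = gamma_from_capillary(0.5e-3, 0.05e-3, 50.0, 0.0)
        assert est.d_gamma / est.gamma == pytest.approx(math.sqrt(2) * 0.1)


class TestPhCalibration:
    def test_exact_cubic_recovered(self):
        coeffs = [0.5, -1.2, 3.0, 7.0]
        ratio = np.linspace(0.5, 2.0, 8)
        ph = np.polyval(coeffs, ratio)
        cal = fit_ph_calibration(np.column_stack([ph, ratio]))
        assert np.allclose(cal.coeffs, coeffs, atol=1e-10)
        assert cal.rms < 1e-10

    def test_sigmoid_round_trip(self):
        rng = np.random.default_rng(5)
        ph = np.linspace(6.8, 8.4, 8)
        ratio = dye_ratio(ph) * (1 + rng.normal(scale=0.002, size=ph.size))
        cal = fit_ph_calibration(np.column_stack([ph, ratio]))
        probe = np.linspace(6.9, 8.3, 50)
        est, oor = cal.ph_from_ratio(dye_ratio(probe))
        assert not oor.any()
        assert np.abs(est - probe).max() < 0.05

    def test_non_monotone_warns_but_fits(self):
        ph = np.linspace(7, 9, 6)
        ratio = np.array([0.5, 0.9, 0.8, 1.2, 1.5, 1.7])
        with pytest.warns(UserWarning, match="monotone"):
            cal = fit_ph_calibration(np.column_stack([ph, ratio]))
        assert not cal.monotone

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="5"):
            fit_ph_calibration([[7.0, 1.0]] * 4)


class TestCorrectAndConvert:
    @staticmethod
    def _cal():
        ph = np.linspace(6.8, 8.4, 8)
        return fit_ph_calibration(np.column_stack([ph, dye_ratio(ph)]))

    def test_identity_vignette_zero_dark(self):
        cal = self._cal()
        ph_true = np.linspace(7.0, 8.2, 30)
        i405 = np.full(30, 1000.0)
        i488 = 1000.0 * dye_ratio(ph_true)
        ph, mask = correct_and_convert((i488, i405), np.ones(30), 0.0, cal)
        assert not mask.any()
        assert np.abs(ph - ph_true).max() < 0.03  # cubic-fit systematics only

    def test_field_round_trip_with_vignette_and_noise(self):
        """2-D chamber image at 2% pixel noise: after width-averaging (the
        chamber-mode reduction) the reconstruction stays within 0.05 pH."""
        ny, nx = 256, 160
        x = np.linspace(0, 1, nx)
        ph_true = 7.2 + 0.8 * x  # the ~1 pH unit a chamber profile spans
        field = np.broadcast_to(ph_true, (ny, nx))
        i488, i405, vignette, meta = gen_ratiometric_field(
            field, vignette_strength=0.3, dark_offset=100.0, noise=0.02,
            spec=SyntheticSpec(41),
        )
        ph, mask = correct_and_convert(
            (i488, i405), vignette, meta["dark_offset"], self._cal()
        )
        profile = width_averaged_profile(ph, axis=0)
        assert np.abs(profile - ph_true).max() < 0.05

    def test_droplet_interior_masked(self):
        cal = self._cal()
        ph_true = np.full(50, 7.5)
        interior = np.zeros(50, bool)
        interior[20:30] = True
        i488, i405, vignette, meta = gen_ratiometric_field(
            ph_true, noise=0.0, droplet_mask=interior, spec=SyntheticSpec(42)
        )
        ph, mask = correct_and_convert((i488, i405), vignette, 100.0, cal)
        assert mask[20:30].all()
        assert np.isnan(ph[20:30]).all()

    def test_nonpositive_vignette_rejected(self):
        cal = self._cal()
        with pytest.raises(ValueError, match="vignette"):
            correct_and_convert(
                (np.ones(5), np.ones(5)), np.zeros(5), 0.0, cal
            )


class TestPhGradient:
    def test_exact_linear_profile(self):
        x = np.linspace(-100e-6, 100e-6, 201)
        ph = 7.5 + 4e3 * x
        fit = fit_ph_gradient(x, ph, edges=(-25e-6, 25e-6))
        assert fit.slope == pytest.approx(4e3, rel=1e-9)
        assert fit.n_points == 30

    def test_inverse_r_profile_slope_at_window(self):
        """For a 1/r far-field cloud the window slope matches the analytic
        derivative at the window centroid within a few percent."""
        R = 25e-6
        x = np.linspace(R, 4 * R, 400)
        amp = 0.5 * R  # pH = 7 + amp/r
        ph = 7.0 + amp / x
        fit = fit_ph_gradient(x, ph, edges=(-R, R), sides=("right",))
        window = np.sort(x[x > R])[:15]
        x_mid = window.mean()
        assert fit.slope == pytest.approx(-amp / x_mid**2, rel=0.05)

    def test_masked_points_skipped(self):
        x = np.linspace(-100e-6, 100e-6, 201)
        ph = 7.5 + 4e3 * x
        ph[np.abs(x) < 30e-6] = np.nan  # droplet interior
        fit = fit_ph_gradient(x, ph, edges=(-25e-6, 25e-6))
        assert fit.slope == pytest.approx(4e3, rel=1e-9)

    def test_insufficient_points_named_side(self):
        x = np.linspace(-100e-6, 100e-6, 41)
        ph = np.full_like(x, 7.5)
        ph[x < -20e-6] = np.nan
        with pytest.raises(ValueError, match="left"):
            fit_ph_gradient(x, ph, edges=(-25e-6, 25e-6))


class TestMaxSpeed:
    def test_constant_speed(self):
        assert max_speed_p95(np.full(100, 2.5e-6)) == pytest.approx(2.5e-6)

    def test_uniform_distribution_quantile(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 1, 200000)
        se = math.sqrt(0.95 * 0.05 / v.size)  # asymptotic quantile SE (f=1)
        assert abs(max_speed_p95(v) - 0.95) < 3 * se

    def test_outliers_above_p95_ignored(self):
        v = np.concatenate([np.linspace(0, 1, 1000), np.full(10, 100.0)])
        with_outliers = max_speed_p95(v)
        assert with_outliers < 1.1

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="20"):
            max_speed_p95(np.ones(10))


class TestAbsorbance:
    def test_known_value(self):
        # BSA at 280 nm: eps = 43.824 / mM / cm
        c = concentration_from_absorbance([0.43824], [100.0], 43.824, 1.0)
        assert c == pytest.approx(1.0)

    def test_zero_absorbance(self):
        assert concentration_from_absorbance([0.0], [1.0], 43.824) == 0.0

    def test_dilution_series_averaged(self):
        # same stock measured at three dilutions
        c_true, eps = 4.5, 43.824
        dil = np.array([200.0, 100.0, 50.0])
        A = c_true / dil * eps
        assert concentration_from_absorbance(A, dil, eps) == pytest.approx(c_true)

    def test_negative_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            c = concentration_from_absorbance([0.4, -0.1], [1.0, 1.0], 1.0)
        assert c == pytest.approx(0.4)
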