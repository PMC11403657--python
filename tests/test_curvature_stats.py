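"""First-moment curvature estimator, blocking errors, and origin fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import constants
from scipy.integrate import quad

from memcurv import (
    CoverageCurvatureSeries,
    CurvatureEstimate,
    CurvatureSlope,
    DomainError,
    InsufficientDataError,
    StressProfile,
    area_fraction,
    blocking_sem,
    fit_through_origin,
    leaflet_flip,
    make_ar1_series,
    make_coverage_dataset,
    moment_timeseries,
    spontaneous_curvature_moment,
)
from memcurv import SeriesRecipe
from memcurv.errors import StateError
from memcurv.units import bar_nm2_to_kbt_per_nm


def profile(z, s):
    return StressProfile(z=z, s=s, exterior_at_positive_z=True, centered=True)


class TestSpontaneousCurvatureMoment:
    def test_even_profile_has_zero_moment(self, symmetric_grid):
        z = symmetric_grid
        p = profile(z, np.exp(-(z**2)))
        assert abs(spontaneous_curvature_moment(p)) < 1e-12

    def test_gaussian_closed_form(self, gaussian_odd_profile):
        # integral z^2 exp(-z^2/(2w^2)) dz = sqrt(2*pi)*w^3 for A = 1, w = 1
        expected_bar_nm2 = -np.sqrt(2.0 * np.pi)
        expected = bar_nm2_to_kbt_per_nm(expected_bar_nm2)
        got = spontaneous_curvature_moment(gaussian_odd_profile)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(-0.05989, rel=1e-3)

    def test_matches_adaptive_quadrature_oracle(self, symmetric_grid):
        rng = np.random.default_rng(3)
        z = symmetric_grid
        for _ in range(20):
            amps = rng.normal(0.0, 50.0, size=3)
            centers = rng.uniform(-3.0, 3.0, size=3)
            widths = rng.uniform(0.5, 1.5, size=3)

            def s_func(x):
                return sum(
                    a * np.exp(-((x - c) ** 2) / (2.0 * w**2))
                    for a, c, w in zip(amps, centers, widths)
                )

            p = profile(z, s_func(z))
            oracle, _ = quad(lambda x: x * s_func(x), z[0], z[-1], limit=400)
            expected = bar_nm2_to_kbt_per_nm(-oracle)
            assert spontaneous_curvature_moment(p) == pytest.approx(expected, rel=1e-6)

    def test_conversion_constant_from_physical_constants(self):
        # 1 bar*nm^2 = 1e-22 J/nm; at 303.15 K this is ~0.023893 kBT/nm
        factor = 1e-22 / (constants.k * 303.15)
        assert bar_nm2_to_kbt_per_nm(1.0) == pytest.approx(factor, rel=1e-12)

    def test_requires_centered_and_oriented(self, symmetric_grid):
        z = symmetric_grid
        with pytest.raises(StateError):
            spontaneous_curvature_moment(StressProfile(z=z, s=z))
        with pytest.raises(StateError):
            spontaneous_curvature_moment(StressProfile(z=z, s=z, centered=True))

    def test_moment_sign_switch(self, gaussian_odd_profile):
        m_minus = spontaneous_curvature_moment(gaussian_odd_profile, moment_sign=-1.0)
        m_plus = spontaneous_curvature_moment(gaussian_odd_profile, moment_sign=1.0)
        assert m_minus == pytest.approx(-m_plus, rel=1e-12)

    def test_linearity(self, symmetric_grid):
        z = symmetric_grid
        rng = np.random.default_rng(5)
        s1 = rng.normal(size=z.size)
        s2 = rng.normal(size=z.size)
        a, b = 2.5, -1.25
        m_combo = spontaneous_curvature_moment(profile(z, a * s1 + b * s2))
        m_parts = a * spontaneous_curvature_moment(profile(z, s1)) + b * spontaneous_curvature_moment(profile(z, s2))
        assert m_combo == pytest.approx(m_parts, rel=1e-9)

    def test_upper_leaflet_bump_has_consistent_sign(self, symmetric_grid):
        """A bulky insertion in the upper headgroup region pushes 2*kappa*m negative."""
        z = symmetric_grid
        base = np.exp(-(z**2))  # symmetric: zero moment
        bump = 10.0 * np.exp(-((z - 2.0) ** 2) / 0.5)  # upper leaflet, z > 0
        m = spontaneous_curvature_moment(profile(z, base + bump))
        assert m < 0
        reflected = profile(z, (base + bump)[::-1])
        assert spontaneous_curvature_moment(reflected) == pytest.approx(-m, rel=1e-9)


class TestMomentTimeseries:
    def test_single_profile(self, gaussian_odd_profile):
        series = moment_timeseries([gaussian_odd_profile])
        assert series.shape == (1,)
        assert series[0] == spontaneous_curvature_moment(gaussian_odd_profile)

    def test_identical_profiles_give_constant_series(self, gaussian_odd_profile):
        series = moment_timeseries([gaussian_odd_profile] * 5)
        assert np.all(series == series[0])

    def test_inconsistent_grids_rejected(self, gaussian_odd_profile):
        other = profile(np.linspace(-4, 4, 81), np.zeros(81))
        with pytest.raises(DomainError):
            moment_timeseries([gaussian_odd_profile, other])


class TestBlockingSem:
    def test_constant_series_has_zero_sem(self):
        sem, plateau = blocking_sem(np.full(64, 3.7))
        assert sem == 0.0
        assert plateau

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            blocking_sem(np.arange(10.0))

    def test_iid_calibration(self):
        """Mean blocking SEM over 200 seeds within 10% of sigma/sqrt(N)."""
        n = 4096
        sems = []
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(n)
            sem, _ = blocking_sem(x)
            sems.append(sem)
        assert np.mean(sems) == pytest.approx(1.0 / np.sqrt(n), rel=0.10)

    def test_ar1_calibration(self):
        """Blocking SEM tracks the analytic SEM of an AR(1) mean at rho = 0.9."""
        rho, n = 0.9, 65536
        analytic = np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        sems = [
            blocking_sem(make_ar1_series(SeriesRecipe(n=n, rho=rho, seed=seed)))[0]
            for seed in range(10)
        ]
        assert np.mean(sems) == pytest.approx(analytic, rel=0.20)

    def test_shuffled_iid_matches_naive_sem(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(2048)
        naive = x.std(ddof=1) / np.sqrt(x.size)
        sem, _ = blocking_sem(rng.permutation(x))
        assert sem == pytest.approx(naive, rel=0.15)


class TestAreaFraction:
    def test_zero_extent_means_zero_coverage(self):
        assert area_fraction(0.0, 5, 10.0) == 0.0

    def test_single_peptide_in_patch(self):
        # disk of diameter 2 nm in the 10.4 nm^2 patch
        assert area_fraction(2.0, 1, 10.4) == pytest.approx(np.pi / 10.4, rel=1e-12)

    def test_doubling_area_halves_phi(self):
        assert area_fraction(1.5, 3, 40.0) == pytest.approx(
            area_fraction(1.5, 3, 20.0) / 2.0, rel=1e-12
        )

    def test_dilute_regime_violation_rejected(self):
        with pytest.raises(DomainError):
            area_fraction(4.0, 10, 10.0)


class TestFitThroughOrigin:
    def test_single_point_interpolated_exactly(self):
        series = CoverageCurvatureSeries(
            points=(CurvatureEstimate(two_kappa_m=0.5, sem=0.0, phi=0.1),)
        )
        fit = fit_through_origin(series)
        assert fit.slope == pytest.approx(5.0)
        assert fit.slope_err == 0.0

    def test_zero_response_gives_zero_slope(self):
        series = CoverageCurvatureSeries(
            points=tuple(
                CurvatureEstimate(two_kappa_m=0.0, sem=0.1, phi=p)
                for p in (0.05, 0.1)
            )
        )
        assert fit_through_origin(series).slope == 0.0

    def test_m0_and_inverse_consistent(self):
        series = CoverageCurvatureSeries(
            points=(CurvatureEstimate(two_kappa_m=-0.4, sem=0.0, phi=0.1),)
        )
        fit = fit_through_origin(series, kappa=25.2)
        assert fit.m0 == pytest.approx(fit.slope / (2 * 25.2), rel=1e-12)
        assert fit.m0 * fit.m0_inv == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_phi_rejected(self):
        series = CoverageCurvatureSeries(
            points=(CurvatureEstimate(two_kappa_m=0.3, sem=0.0, phi=0.0),)
        )
        with pytest.raises(DomainError):
            fit_through_origin(series)

    def test_mixed_sems_rejected(self):
        series = CoverageCurvatureSeries(
            points=(
                CurvatureEstimate(two_kappa_m=0.3, sem=0.0, phi=0.05),
                CurvatureEstimate(two_kappa_m=0.6, sem=0.1, phi=0.1),
            )
        )
        with pytest.raises(DomainError):
            fit_through_origin(series)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_equivariance_under_scaling(self, scale):
        base = make_coverage_dataset(-8.0, [0.02, 0.05], [0.05, 0.08], seed=1)
        fit = fit_through_origin(base)
        scaled_y = CoverageCurvatureSeries(
            points=tuple(
                CurvatureEstimate(
                    two_kappa_m=p.two_kappa_m * scale, sem=p.sem, phi=p.phi
                )
                for p in base.points
            )
        )
        assert fit_through_origin(scaled_y).slope == pytest.approx(
            fit.slope * scale, rel=1e-9
        )
        scaled_x = CoverageCurvatureSeries(
            points=tuple(
                CurvatureEstimate(
                    two_kappa_m=p.two_kappa_m, sem=p.sem, phi=p.phi * scale / 20
                )
                for p in base.points
            )
        )
        assert fit_through_origin(scaled_x).slope == pytest.approx(
            fit.slope * 20 / scale, rel=1e-9
        )

    def test_planted_slope_recovery_and_ci_coverage(self):
        """~95% CI coverage of the weighted origin fit over 500 replicates."""
        planted = -8.0
        phis, sems = [0.02, 0.05], [0.05, 0.08]
        hits = 0
        slopes = []
        for seed in range(500):
            series = make_coverage_dataset(planted, phis, sems, seed=seed)
            fit = fit_through_origin(series)
            slopes.append(fit.slope)
            if abs(fit.slope - planted) <= 1.96 * fit.slope_err:
                hits += 1
        fit0 = fit_through_origin(make_coverage_dataset(planted, phis, sems, seed=0))
        assert abs(np.mean(slopes) - planted) < 3 * fit0.slope_err
        assert 0.93 <= hits / 500 <= 0.97


class TestLeafletFlip:
    def test_sign_flip(self):
        est = CurvatureEstimate(two_kappa_m=-0.4, sem=0.02, phi=0.1, label="POPG")
        flipped = leaflet_flip(est)
        assert flipped.two_kappa_m == 0.4
        assert flipped.sem == est.sem
        assert "inner-leaflet" in flipped.label

    def test_involution(self):
        est = CurvatureEstimate(two_kappa_m=-0.4, sem=0.02, phi=0.1, label="POPG")
        assert leaflet_flip(leaflet_flip(est)) == est

    def test_flip_commutes_with_fit(self):
        series = make_coverage_dataset(-8.0, [0.02, 0.05], [0.05, 0.08], seed=9)
        a = leaflet_flip(fit_through_origin(series))
        b = fit_through_origin(leaflet_flip(series))
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.slope_err == pytest.approx(b.slope_err, rel=1e-12)
        assert a.m0 == pytest.approx(b.m0, rel=1e-12)
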