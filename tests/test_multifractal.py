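"""Closed-form fields: scale relation, nondimensionalization, boundary and
initial conditions, normalization, PDE residual oracle, mass-release law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mfrelease.multifractal import (
    HydroParams,
    ReleaseModelParams,
    ScaleParams,
    cumulative_release,
    density_field,
    dimensional_density,
    dimensional_velocity,
    fractality_from_sigma,
    mass_release_rate,
    nondimensionalize,
    pde_residual,
    pde_residual_max,
    sigma_from_scale,
    to_nondim_coords,
    velocity_field,
)


class TestScaleRelation:
    @pytest.mark.parametrize(
        "lam, dt, f_alpha, expected",
        [
            (0.0, 0.1, 2.0, 0.0),  # zero coefficient: non-fractal limit
            (3.0, 0.1, 2.0, 3.0),  # exponent (2/2)-1 vanishes
            (1.0, 0.1, 1.0, 0.1),  # exponent 1
        ],
    )
    def test_sigma_examples(self, lam, dt, f_alpha, expected):
        assert sigma_from_scale(ScaleParams(lam, dt, f_alpha)) == pytest.approx(
            expected, abs=1e-15
        )

    @pytest.mark.parametrize("bad", [
        dict(lam=-1.0, dt=0.1, f_alpha=1.0),
        dict(lam=1.0, dt=0.0, f_alpha=1.0),
        dict(lam=1.0, dt=0.1, f_alpha=-2.0),
    ])
    def test_invalid_scale_params(self, bad):
        with pytest.raises(ValueError):
            ScaleParams(**bad)

    @pytest.mark.parametrize(
        "sigma, lam, dt, expected",
        [(3.0, 3.0, 0.1, 2.0), (0.1, 1.0, 0.1, 1.0)],
    )
    def test_fractality_inversion_examples(self, sigma, lam, dt, expected):
        assert fractality_from_sigma(sigma, lam, dt) == pytest.approx(expected)

    @pytest.mark.parametrize("f", [0.5, 1.0, 1.5, 2.0, 3.0])
    def test_round_trip_fixed(self, f):
        scale = ScaleParams(lam=2.5, dt=0.1, f_alpha=f)
        sigma = sigma_from_scale(scale)
        assert fractality_from_sigma(sigma, 2.5, 0.1) == pytest.approx(
            f, rel=1e-10
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        f=st.floats(0.3, 5.0),
        lam=st.floats(1e-3, 1e3),
        dt=st.floats(0.01, 0.9),
    )
    def test_round_trip_property(self, f, lam, dt):
        sigma = sigma_from_scale(ScaleParams(lam, dt, f))
        assert fractality_from_sigma(sigma, lam, dt) == pytest.approx(
            f, rel=1e-9
        )

    def test_inversion_domain_errors(self):
        with pytest.raises(ValueError):
            fractality_from_sigma(1.0, 1.0, 1.0)  # dt = 1 unidentifiable
        with pytest.raises(ValueError):
            fractality_from_sigma(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            fractality_from_sigma(1.0, -1.0, 0.1)


class TestNondimensionalization:
    @pytest.mark.parametrize(
        "v0, alpha, sigma, tau0, mu, phi",
        [
            (1.0, 1.0, 0.0, 1.0, 0.0, 1.0),
            (2.0, 1.0, 1.0, 1.0, 1.0, 0.5),
            (1.0, 2.0, 2.0, 1.0, 0.5, 2.0),
        ],
    )
    def test_examples(self, v0, alpha, sigma, tau0, mu, phi):
        nd = nondimensionalize(HydroParams(v0, alpha, sigma, tau0))
        assert nd.mu == pytest.approx(mu)
        assert nd.phi == pytest.approx(phi)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError):
            nondimensionalize(HydroParams(0.0, 1.0, 1.0, 1.0))

    def test_coordinate_round_trip(self):
        from mfrelease.multifractal import from_nondim_coords

        h = HydroParams(v0=2.0, alpha=0.7, sigma=0.3, tau0=1.7)
        x = np.linspace(-3, 9, 17)
        t = np.linspace(0, 11, 17)
        xi, eta = to_nondim_coords(x, t, h)
        x2, t2 = from_nondim_coords(xi, eta, h)
        np.testing.assert_allclose(x2, x, rtol=1e-14)
        np.testing.assert_allclose(t2, t, rtol=1e-14)


class TestFields:
    def test_velocity_comoving_boundary(self):
        eta = np.linspace(0, 10, 25)
        for mu in (0.0, 0.7, 3.0):
            np.testing.assert_allclose(velocity_field(mu, eta, eta), 1.0)

    def test_velocity_initial_condition(self):
        assert velocity_field(0.7, 3.0, 0.0) == 1.0

    def test_velocity_value(self):
        assert velocity_field(1.0, 2.0, 1.0) == pytest.approx(1.5)

    def test_density_peak_and_values(self):
        assert density_field(0.9, 1.3, 0.0, 0.0) == pytest.approx(1.0)
        assert density_field(0.0, 1.0, 2.0, 1.0) == pytest.approx(math.exp(-1))
        # comoving point xi = eta at eta = 2, mu = 1
        assert density_field(1.0, 1.0, 2.0, 2.0) == pytest.approx(5.0**-0.5)
        with pytest.raises(ValueError):
            density_field(1.0, 0.0, 0.0, 0.0)

    def test_dimensional_density_initial_condition(self):
        h = HydroParams(1.0, 1.0, 1.0, 1.0)
        assert dimensional_density(0.0, 0.0, h) == pytest.approx(math.pi**-0.5)
        # Gaussian of width alpha at t = 0
        x = np.linspace(-4, 4, 33)
        expected = math.pi**-0.5 / h.alpha * np.exp(-((x / h.alpha) ** 2))
        np.testing.assert_allclose(dimensional_density(x, 0.0, h), expected)

    def test_dimensional_density_comoving_peak(self):
        h = HydroParams(v0=1.3, alpha=0.8, sigma=0.6, tau0=1.0)
        t = 5.0
        d = h.alpha**2 + (h.sigma / h.alpha) ** 2 * t**2
        assert dimensional_density(h.v0 * t, t, h) == pytest.approx(
            math.pi**-0.5 * d**-0.5
        )

    def test_density_vanishes_at_infinity(self):
        h = HydroParams(1.0, 1.0, 0.5, 1.0)
        assert dimensional_density(1e6, 3.0, h) == pytest.approx(0.0, abs=1e-300)
        assert dimensional_density(-1e6, 3.0, h) == pytest.approx(0.0, abs=1e-300)

    def test_normalization(self):
        h = HydroParams(v0=1.0, alpha=0.7, sigma=0.4, tau0=1.0)
        val, _ = quad(lambda x: dimensional_density(x, 3.0, h), -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_dimensional_velocity_initial_and_boundary(self):
        h = HydroParams(v0=1.7, alpha=1.0, sigma=0.5, tau0=1.0)
        x = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(dimensional_velocity(x, 0.0, h), h.v0)
        t = np.linspace(0, 9, 10)
        np.testing.assert_allclose(dimensional_velocity(h.v0 * t, t, h), h.v0)

    def test_dimensional_nondimensional_consistency(self):
        h = HydroParams(v0=1.4, alpha=0.9, sigma=0.35, tau0=2.0)
        nd = nondimensionalize(h)
        x = np.linspace(-3, 8, 10)
        t = np.linspace(0, 6, 10)
        xx, tt = np.meshgrid(x, t)
        xi, eta = to_nondim_coords(xx, tt, h)
        v_dim = dimensional_velocity(xx, tt, h)
        np.testing.assert_allclose(
            v_dim, h.v0 * velocity_field(nd.mu, xi, eta), rtol=1e-12
        )
        rho_dim = dimensional_density(xx, tt, h)
        np.testing.assert_allclose(
            rho_dim,
            density_field(nd.mu, nd.phi, xi, eta) / (math.pi**0.5 * h.alpha),
            rtol=1e-12,
        )

    def test_non_fractal_limit_rigid_translation(self):
        h = HydroParams(v0=1.0, alpha=1.2, sigma=0.0, tau0=1.0)
        x = np.linspace(-4, 8, 41)
        for t in (0.0, 1.0, 5.0):
            np.testing.assert_allclose(
                dimensional_density(x, t, h),
                dimensional_density(x - h.v0 * t, 0.0, h),
                rtol=1e-12,
            )
            np.testing.assert_allclose(dimensional_velocity(x, t, h), h.v0)


class TestPdeOracle:
    def test_second_order_convergence(self):
        h = HydroParams(v0=1.0, alpha=1.0, sigma=0.5, tau0=1.0)
        maxima = []
        for n in (51, 101, 201):
            x = np.linspace(-5, 10, n)
            t = np.linspace(0, 5, n)
            maxima.append(pde_residual_max(h, x, t))
        for coarse, fine in zip(maxima, maxima[1:]):
            assert 3.0 <= coarse[0] / fine[0] <= 5.0  # momentum
            assert 3.0 <= coarse[1] / fine[1] <= 5.0  # continuity

    def test_fine_grid_residuals_small(self):
        h = HydroParams(v0=1.0, alpha=1.0, sigma=0.5, tau0=1.0)
        x = np.linspace(-5, 10, 201)
        t = np.linspace(0, 5, 201)
        mom, cont = pde_residual_max(h, x, t)
        assert mom < 2e-3
        assert cont < 2e-3

    def test_pure_transport_when_sigma_zero(self):
        h = HydroParams(v0=1.0, alpha=1.0, sigma=0.0, tau0=1.0)
        conts = []
        for n in (51, 101):
            x = np.linspace(-5, 10, n)
            t = np.linspace(0, 5, n)
            mom, cont = pde_residual_max(h, x, t)
            assert mom == 0.0  # no quantum-like term, fields are exact
            conts.append(cont)
        assert 3.0 <= conts[0] / conts[1] <= 5.0

    def test_coarse_grid_rejected(self):
        h = HydroParams(1.0, 1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            pde_residual(h, np.linspace(0, 1, 4), np.linspace(0, 1, 10))


class TestMassRelease:
    def test_rate_vanishes_at_start(self):
        p = ReleaseModelParams(mu=1.3, phi=0.8, m0_bar=1.0)
        assert mass_release_rate(p, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_rate_nonfractal_value(self):
        p = ReleaseModelParams(mu=0.0, phi=1.0, m0_bar=1.0)
        assert mass_release_rate(p, 1.0) == pytest.approx(2.0 * math.exp(-1))

    def test_rate_matches_finite_difference(self):
        p = ReleaseModelParams(mu=1.2, phi=0.9, m0_bar=0.7, xi_obs=0.3)
        eta = np.linspace(0.05, 5.0, 60)
        d = 1e-6
        fd = -(
            density_field(p.mu, p.phi, p.xi_obs, eta + d)
            - density_field(p.mu, p.phi, p.xi_obs, eta - d)
        ) / (2 * d) * p.m0_bar
        np.testing.assert_allclose(mass_release_rate(p, eta), fd, atol=1e-6)

    def test_rate_nonnegative_at_matrix(self):
        eta = np.linspace(0, 20, 200)
        for mu in (0.0, 0.3, 2.0):
            p = ReleaseModelParams(mu=mu, phi=1.3, m0_bar=1.0)
            assert np.all(mass_release_rate(p, eta) >= -1e-14)

    def test_cumulative_limits(self):
        p = ReleaseModelParams(mu=1.0, phi=1.0, m0_bar=1.0)
        assert cumulative_release(p, 0.0) == 0.0
        assert cumulative_release(p, 1e6) == pytest.approx(1.0, abs=1e-5)

    def test_cumulative_nonfractal_value(self):
        p = ReleaseModelParams(mu=0.0, phi=1.0, m0_bar=1.0)
        assert cumulative_release(p, 1.0) == pytest.approx(1 - math.exp(-1))

    def test_cumulative_monotone_and_bounded(self):
        eta = np.linspace(0, 50, 500)
        for mu, phi, m0 in [(0.0, 1.0, 0.5), (0.4, 2.0, 1.0), (3.0, 0.5, 0.8)]:
            p = ReleaseModelParams(mu=mu, phi=phi, m0_bar=m0)
            m = cumulative_release(p, eta)
            assert np.all(np.diff(m) >= -1e-14)
            assert np.all(m <= m0 + 1e-12)

    def test_cumulative_derivative_consistent_with_rate(self):
        p = ReleaseModelParams(mu=0.8, phi=1.1, m0_bar=0.9)
        eta = np.linspace(0.1, 8.0, 40)
        d = 1e-5
        fd = (
            cumulative_release(p, eta + d) - cumulative_release(p, eta - d)
        ) / (2 * d)
        rho0 = density_field(p.mu, p.phi, p.xi_obs, 0.0)
        np.testing.assert_allclose(fd, mass_release_rate(p, eta) / rho0, atol=1e-8)

    def test_negative_eta_rejected(self):
        p = ReleaseModelParams(mu=1.0, phi=1.0, m0_bar=1.0)
        with pytest.raises(ValueError):
            cumulative_release(p, -0.5)
        with pytest.raises(ValueError):
            mass_release_rate(p, -0.5)
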