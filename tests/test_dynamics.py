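"""Model right-hand sides: nonlinearities, conservation, linearization."""

import numpy as np
import pytest

from citypatterns import (
    ModelParams,
    ScalarField,
    SpatialGrid,
    attractiveness,
    movement_rhs,
    population_rhs,
    service_rhs,
    sigma,
    sigma_prime,
)
from citypatterns.dynamics import RhsEvaluator
from citypatterns.errors import (
    GridMismatchError,
    InvariantViolationError,
    ParameterError,
)
from citypatterns.stability import homogeneous_state, linearization_at_k

from conftest import random_admissible_fields


class TestParams:
    def test_mu_below_one_rejected(self):
        with pytest.raises(ParameterError):
            ModelParams.defaults("base", mu=0.8)

    def test_base_variant_forbids_competition_terms(self):
        with pytest.raises(ParameterError):
            ModelParams(variant="base", a_p=1.5)
        with pytest.raises(ParameterError):
            ModelParams(variant="base", alpha1=1e-5)

    def test_defaults_match_tables(self, competition_params):
        assert competition_params.D == 2.0
        assert competition_params.f == 0.05
        assert competition_params.g == 2.0
        assert competition_params.lam == 20000.0
        assert competition_params.mu == 3.0
        assert (competition_params.beta_s, competition_params.beta_p1,
                competition_params.beta_p2) == (5.0, 1.0, 10.0)
        assert competition_params.a_p == 1.5
        assert competition_params.alpha1 == 1.5e-5


class TestSigma:
    def test_anchor_values(self, base_params):
        assert sigma(0.0, base_params) == 0.0
        assert sigma(base_params.lam, base_params) == pytest.approx(1 - 1 / np.e, rel=1e-12)
        # London-calibrated steepness: mean density 8400 with service share 0.06
        p32 = ModelParams.defaults("base", mu=3.2)
        assert sigma(8400.0, p32) == pytest.approx(0.060, abs=1e-3)

    def test_monotone_and_bounded(self, base_params):
        P = np.linspace(0, 5e4, 500)
        out = sigma(P, base_params)
        assert np.all(np.diff(out) > 0)
        assert np.all((out >= 0) & (out < 1))

    def test_negative_rejected(self, base_params):
        with pytest.raises(ParameterError):
            sigma(-1.0, base_params)
        with pytest.raises(ParameterError):
            sigma_prime(np.array([2.0, -3.0]), base_params)

    def test_sigma_prime_closed_form_and_fd(self, base_params):
        lam, mu = base_params.lam, base_params.mu
        assert sigma_prime(lam, base_params) == pytest.approx((mu / lam) / np.e, rel=1e-12)
        assert sigma_prime(0.0, base_params) == 0.0
        h = 1e-3
        fd = (sigma(8000 + h, base_params) - sigma(8000 - h, base_params)) / (2 * h)
        assert sigma_prime(8000.0, base_params) == pytest.approx(fd, rel=1e-6)


class TestAttractiveness:
    @pytest.mark.parametrize("s0,expected", [(0.0, 0.0), (1.0, 0.0), (0.3, 0.21)])
    def test_homogeneous(self, base_params, line_grid, s0, expected):
        s = ScalarField.constant(line_grid, s0, role="service")
        A = attractiveness(s, base_params)
        np.testing.assert_allclose(A.values, expected, atol=1e-14)

    def test_rejects_out_of_range(self, base_params, line_grid):
        s = ScalarField.constant(line_grid, 0.5)
        s.values[3] = 1.5
        with pytest.raises(InvariantViolationError):
            attractiveness(s, base_params)


class TestMovement:
    def test_homogeneous_is_fixed(self, base_params, line_grid):
        p = ScalarField.constant(line_grid, 8000.0, role="population")
        s = ScalarField.constant(line_grid, 0.3, role="service")
        out = movement_rhs(p, s, base_params)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("variant", ["base", "competition"])
    @pytest.mark.parametrize("dim", [1, 2])
    def test_mass_conserved_for_arbitrary_fields(self, rng, variant, dim):
        params = ModelParams.defaults(variant)
        grid = SpatialGrid.line(200.0, 256) if dim == 1 else SpatialGrid.square(150.0, 48)
        p, s = random_admissible_fields(grid, rng)
        out = population_rhs(p, s, params)
        assert abs(out.total()) < 1e-9 * p.total()

    def test_grid_mismatch(self, base_params):
        p = ScalarField.constant(SpatialGrid.line(200.0, 64), 1.0, role="population")
        s = ScalarField.constant(SpatialGrid.line(200.0, 128), 0.1, role="service")
        with pytest.raises(GridMismatchError):
            movement_rhs(p, s, base_params)


class TestService:
    def test_equilibrium_when_s_equals_sigma(self, base_params, line_grid, rng):
        p, _ = random_admissible_fields(line_grid, rng)
        ev = RhsEvaluator(line_grid, base_params)
        P = np.maximum(
            np.fft.irfft(np.fft.rfft(p.values) * ev._hat_s, n=line_grid.points[0]), 0.0
        )
        s = ScalarField(line_grid, np.asarray(sigma(P, base_params)), role="service")
        out = service_rhs(p, s, base_params)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_innovation_rate_from_bare_land(self, base_params, line_grid):
        p = ScalarField.constant(line_grid, 8000.0, role="population")
        s = ScalarField.constant(line_grid, 0.0, role="service")
        out = service_rhs(p, s, base_params)
        expected = base_params.f * sigma(8000.0, base_params)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)
        assert expected == pytest.approx(3.10e-3, abs=1e-5)

    def test_heaviside_gate_shuts_innovation(self, competition_params, line_grid):
        # below the extinction threshold sigma(p) < alpha1 p: no innovators,
        # and with s = 0 the imitator term vanishes too
        p = ScalarField.constant(line_grid, 5000.0, role="population")
        s = ScalarField.constant(line_grid, 0.0, role="service")
        out = service_rhs(p, s, competition_params)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    @pytest.mark.parametrize("variant", ["base", "competition"])
    def test_bound_preservation(self, rng, variant):
        """ds/dt >= 0 wherever s = 0 and <= 0 wherever s = 1."""
        params = ModelParams.defaults(variant)
        grid = SpatialGrid.line(200.0, 256)
        p, _ = random_admissible_fields(grid, rng)
        for s0, sign in ((0.0, 1.0), (1.0, -1.0)):
            s = ScalarField.constant(grid, s0, role="service")
            out = service_rhs(p, s, params)
            assert np.all(sign * out.values >= -1e-14)


class TestGrowth:
    def test_homogeneous_steady_state_is_fixed_point(self, growth_params):
        grid = SpatialGrid.line(200.0, 128)
        st = homogeneous_state(growth_params)
        assert st.p0 == pytest.approx(1.16e4, rel=1e-2)
        assert st.s0 == pytest.approx(3.9e-3, rel=3e-2)
        p = ScalarField.constant(grid, st.p0, role="population")
        s = ScalarField.constant(grid, st.s0, role="service")
        assert np.max(np.abs(population_rhs(p, s, growth_params).values)) < 1e-10 * st.p0
        assert np.max(np.abs(service_rhs(p, s, growth_params).values)) < 1e-10

    def test_carrying_capacity_with_no_services_is_fixed(self, growth_params):
        grid = SpatialGrid.line(200.0, 128)
        p = ScalarField.constant(grid, growth_params.c, role="population")
        s = ScalarField.constant(grid, 0.0, role="service")
        out = population_rhs(p, s, growth_params)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)


def _fd_mode_jacobian(params, p0, s0, k, grid_n=512, L=200.0, eps_p_rel=1e-5, eps_s=1e-8):
    """Central-difference linearization about a uniform state on one mode."""
    g = SpatialGrid.line(L, grid_n)
    x = g.axes()[0]
    mode = np.cos(k * x)
    ev = RhsEvaluator(g, params)

    def proj(f):
        return 2.0 * np.mean(f * mode)

    J = np.zeros((2, 2))
    eps_p = eps_p_rel * max(p0, 1.0)
    for j, (ep, es) in enumerate([(eps_p, 0.0), (0.0, eps_s)]):
        dp_hi, ds_hi = ev.both(p0 + ep * mode, s0 + es * mode)
        dp_lo, ds_lo = ev.both(p0 - ep * mode, s0 - es * mode)
        h = 2.0 * (ep if j == 0 else es)
        J[0, j] = proj(dp_hi - dp_lo) / h
        J[1, j] = proj(ds_hi - ds_lo) / h
    return J


class TestLinearizationOracle:
    """The analytic per-mode matrix is the package's core oracle: it must
    agree with a finite-difference linearization of the nonlinear operator.

    For the gated variants the steady state sits exactly on the Heaviside
    switch, where the operator is only one-sidedly differentiable; the
    comparison is therefore made at a nearby gate-open uniform state, where
    both sides are smooth.
    """

    @pytest.mark.parametrize("variant", ["base", "competition", "growth"])
    @pytest.mark.parametrize("m", [2, 10, 40])
    def test_fd_matches_analytic(self, variant, m):
        params = ModelParams.defaults(variant)
        L = 200.0
        k = 2 * np.pi * m / L
        if variant == "base":
            st = homogeneous_state(params, 8000.0)
            p0, s0 = st.p0, st.s0
        else:
            st = homogeneous_state(params, 12000.0 if variant == "competition" else None)
            # displace into the gate-open region (deficit > 0), staying
            # uniform so the analytic linearization is still exact
            p0, s0 = st.p0, max(st.s0 - 1e-3, 0.0)
        J_analytic = linearization_at_k(p0, s0, params, k, gate_open=True)
        J_fd = _fd_mode_jacobian(params, p0, s0, k)
        err = np.abs(J_fd - J_analytic) / np.maximum(np.abs(J_analytic), 1e-10)
        assert err.max() < 1e-6
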