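"""The three solution strategies and the Lagrange-inversion series."""

import math

import numpy as np
import pytest

from steadycirc import (
    NoSolutionError,
    SpecialCaseError,
    composite_flow_line,
    conservation_coefficients,
    lagrange_series,
    reduced_mu_lambda,
    set_parameter,
    solve_2d,
    solve_general,
    solve_z,
    steady_state,
    surface_grids,
)
from steadycirc.solvers import _z_residual

from helpers import random_model


def brute_force_z(mu, lam, n=1_000_001):
    """Independent oracle: bracket the root by a dense grid sign scan,
    then bisect the bracketing cell to convergence."""
    Z = np.linspace(1e-9, 1 - 1e-9, n)
    f = Z - mu - lam * np.log((1 - Z) / Z)
    (idx,) = np.nonzero(np.diff(np.sign(f)) != 0)
    assert len(idx) == 1, "expected exactly one sign change"
    lo, hi = Z[idx[0]], Z[idx[0] + 1]
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _z_residual(mid, mu, lam) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSolveZ:
    @pytest.mark.parametrize(
        "mu, lam, expected",
        [
            (0.326, 0.0838, 0.370),  # normal reference state
            (0.536, 0.138, 0.523),  # resistance-redistribution state
            (0.372, 0.0838, 0.404),  # lowered-chest-pressure state
        ],
    )
    def test_reference_roots(self, mu, lam, expected):
        assert solve_z(mu, lam) == pytest.approx(expected, abs=5e-4)

    def test_symmetric_point_is_exact(self):
        # at Z = 1/2 the log term vanishes identically
        assert solve_z(0.5, 0.31) == pytest.approx(0.5, abs=1e-13)

    def test_against_brute_force_scan(self):
        assert solve_z(0.9, 0.3) == pytest.approx(
            brute_force_z(0.9, 0.3), abs=1e-10
        )

    def test_lambda_zero_degenerates_to_mu(self):
        assert solve_z(0.37, 0.0) == 0.37
        with pytest.raises(NoSolutionError):
            solve_z(1.3, 0.0)

    def test_monotone_increasing_in_mu(self):
        roots = [solve_z(mu, 0.0838) for mu in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(roots) > 0)

    @pytest.mark.parametrize("mu", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.5])
    def test_unique_sign_change_on_grid(self, mu, lam):
        Z = np.linspace(1e-9, 1 - 1e-9, 100_001)
        f = Z - mu - lam * np.log((1 - Z) / Z)
        assert np.count_nonzero(np.diff(np.sign(f)) != 0) == 1

    def test_residual_below_tolerance_at_root(self):
        z = solve_z(0.326, 0.0838)
        assert abs(_z_residual(z, 0.326, 0.0838)) < 1e-12


class TestGeneralSolver:
    def test_reference_cardiac_output(self, reference_model):
        assert solve_general(reference_model) == pytest.approx(5.0, abs=0.05)

    def test_balanced_equivalence_with_solve_z(self, reference_model):
        rf = reduced_mu_lambda(reference_model)
        K = reference_model.right_heart.K
        assert solve_general(reference_model) == pytest.approx(
            K * solve_z(rf.mu, rf.lam), rel=1e-9
        )

    def test_unbalanced_model_against_grid_scan(self, reference_model):
        m = set_parameter(reference_model, "K_L", 10.0)
        rf = conservation_coefficients(m)
        from steadycirc.solvers import _general_residual

        # coarse scan to bracket the root, dense vectorized scan inside
        coarse = np.linspace(1e-6, 10.0 - 1e-6, 101)
        f = np.array([_general_residual(q, m, rf) for q in coarse])
        (idx,) = np.nonzero(np.diff(np.sign(f)) != 0)
        lo, hi = coarse[idx[0]], coarse[idx[0] + 1]
        fine = np.linspace(lo, hi, 1_000_001)
        r, l = m.right_heart, m.left_heart
        ffine = (
            rf.CR * fine - rf.D + rf.CS * r.P_ext + rf.CP * l.P_ext
            - (rf.CS / r.beta) * np.log((r.K - fine) / (r.alpha * fine))
            - (rf.CP / l.beta) * np.log((l.K - fine) / (l.alpha * fine))
        )
        (jdx,) = np.nonzero(np.diff(np.sign(ffine)) != 0)
        bracket = (fine[jdx[0]], fine[jdx[0] + 1])
        Q_solved = solve_general(m)
        assert bracket[0] - 1e-6 <= Q_solved <= bracket[1] + 1e-6

    def test_reduced_form_needs_balance(self, reference_model):
        m = set_parameter(reference_model, "K_L", 10.0)
        with pytest.raises(SpecialCaseError):
            reduced_mu_lambda(m)


class TestCompositeFlowLine:
    def test_passes_through_reference_solution(self, reference_model):
        line = composite_flow_line(reference_model)
        assert line.q_at(0.0) == pytest.approx(5.0, abs=0.05)
        assert line.B > 0

    def test_case1_point(self, scenario_models):
        line = composite_flow_line(scenario_models["case1"])
        assert line.q_at(0.70) == pytest.approx(7.1, abs=0.1)

    def test_2d_intersection_matches_general(self, reference_model):
        P_R, Q = solve_2d(reference_model)
        assert Q == pytest.approx(solve_general(reference_model), rel=1e-8)
        assert P_R == pytest.approx(
            reference_model.right_heart.inverse(Q), abs=1e-8
        )

    def test_case2_intersection(self, scenario_models):
        P_R, Q = solve_2d(scenario_models["case2"])
        assert P_R == pytest.approx(-3.8, abs=0.1)
        assert Q == pytest.approx(5.5, abs=0.1)


class TestCrossSolverAgreement:
    @pytest.mark.parametrize("balanced", [True, False])
    def test_hundred_random_models(self, balanced):
        """General solver, 2-D intersection and (balanced) K*solve_z agree
        to 1e-8 relative, and recover the constructed solution."""
        rng = np.random.default_rng(42 if balanced else 43)
        for _ in range(50):
            model, Q_star = random_model(rng, balanced=balanced)
            Q1 = solve_general(model)
            _, Q2 = solve_2d(model)
            assert Q2 == pytest.approx(Q1, rel=1e-8)
            assert Q1 == pytest.approx(Q_star, rel=1e-7)
            if balanced:
                rf = reduced_mu_lambda(model)
                K = model.right_heart.K
                assert K * solve_z(rf.mu, rf.lam) == pytest.approx(Q1, rel=1e-8)

    def test_conservation_at_random_solutions(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model, _ = random_model(rng, balanced=bool(rng.integers(2)))
            state = steady_state(model)
            assert abs(state.residual_volume) < 1e-8
            assert abs(state.flow_mismatch_right) < 1e-9
            assert abs(state.flow_mismatch_left) < 1e-9


class TestSurfaceGrids:
    def test_conservation_plane_value_at_reference_point(self, reference_model):
        grids = surface_grids(reference_model, (-6, 6), (-2, 10), 13)
        # grid node (P_R=0, P_L=4) exists exactly for these ranges/counts
        i = np.argmin(np.abs(grids.P_R - 0.0))
        j = np.argmin(np.abs(grids.P_L - 4.0))
        assert grids.q_plane[i, j] == pytest.approx(5.0, abs=0.05)

    def test_right_sheet_constant_along_pl_and_anchored_at_pext(
        self, reference_model
    ):
        r = reference_model.right_heart
        grids = surface_grids(reference_model, (r.P_ext, r.P_ext + 1), (0, 1), 5)
        assert np.allclose(grids.q_right[0, :], r.K / (1 + r.alpha))
        assert np.ptp(grids.q_right, axis=1).max() == 0.0

    def test_plane_gradient_is_minus_cs_over_cr(self, reference_model):
        grids = surface_grids(reference_model, (-2, 2), (-2, 2), 9)
        slope = np.diff(grids.q_plane, axis=0) / np.diff(grids.P_R)[0]
        assert slope == pytest.approx(-0.182 / 0.258, abs=0.01)

    def test_invalid_inputs(self, reference_model):
        from steadycirc import DomainError

        with pytest.raises(DomainError):
            surface_grids(reference_model, (0, 1), (0, 1), 1)
        with pytest.raises(DomainError):
            surface_grids(reference_model, (1, 1), (0, 1), 5)


class TestLagrangeSeries:
    def test_order_zero_is_mu(self):
        s = lagrange_series(0.326, 0.0838, order=0)
        assert s.terms == (0.326,)
        assert s.value == 0.326

    def test_first_order_term_is_log_ratio(self):
        s = lagrange_series(0.3, 0.05, order=1)
        assert s.terms[1] == pytest.approx(math.log(0.7 / 0.3), rel=1e-12)

    def test_order4_close_to_root_at_reference_parameters(self):
        s = lagrange_series(0.326, 0.0838, order=4)
        assert abs(s.value - solve_z(0.326, 0.0838)) < 5e-3

    def test_symmetric_point_kills_all_corrections(self):
        s = lagrange_series(0.5, 0.3, order=5)
        assert s.value == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "mu, lam",
        # the effective expansion parameter is ~ lam/(mu*(1-mu)); monotone
        # order-4 improvement holds where it stays below ~0.4
        [(mu, lam) for mu in (0.2, 0.35, 0.5, 0.65, 0.8) for lam in (0.02, 0.05)]
        + [(mu, 0.0838) for mu in (0.35, 0.5, 0.65)],
    )
    def test_error_nonincreasing_in_order(self, mu, lam):
        """Truncation error shrinks monotonically through order 4 in the
        small-lambda regime."""
        z = solve_z(mu, lam)
        errors = [abs(lagrange_series(mu, lam, k).value - z) for k in range(5)]
        assert all(
            e2 <= e1 + 1e-15 for e1, e2 in zip(errors, errors[1:])
        ), errors

    def test_domain_errors(self):
        from steadycirc import DomainError

        with pytest.raises(DomainError):
            lagrange_series(1.2, 0.05)
        with pytest.raises(DomainError):
            lagrange_series(0.3, 0.05, order=-1)
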