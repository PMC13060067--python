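"""Monotone cone and monotone-additive projections, df counting, missing-well prediction."""

import numpy as np
import pytest
from scipy.optimize import isotonic_regression
from scipy.special import expit

from sir import (
    AdditiveFit,
    TransformedGrid,
    effective_df,
    fit_isotonic_2d,
    fit_monotone_additive,
    predict_missing,
    transform_responses,
)

from .conftest import isotonic_bruteforce, make_grid


def tg_from(Z, W=None):
    return TransformedGrid.from_arrays(np.asarray(Z, dtype=float), W)


class TestIsotonic2D:
    def test_monotone_input_is_fixed_point(self):
        Z = np.array([[3.0, 2.0, 1.0], [2.5, 1.5, 0.5]])
        fit = fit_isotonic_2d(tg_from(Z))
        np.testing.assert_allclose(fit.theta_iso, Z, atol=1e-9)
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_single_row_matches_pava(self):
        Z = np.array([[0.0, 1.0]])
        fit = fit_isotonic_2d(tg_from(Z))
        np.testing.assert_allclose(fit.theta_iso, [[0.5, 0.5]], atol=1e-9)

    def test_2x2_checkerboard(self):
        # exhaustively derivable optimum: pool all but the free corner
        fit = fit_isotonic_2d(tg_from([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(
            fit.theta_iso, [[1.0, 1 / 3], [1 / 3, 1 / 3]], atol=1e-8
        )
        assert fit.objective == pytest.approx(2 / 3, abs=1e-8)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_bruteforce_kkt_oracle_3x3(self, trial):
        """QP solution equals exhaustive active-set enumeration on random 3x3 grids."""
        rng = np.random.default_rng(100 + trial)
        Z = rng.normal(size=(3, 3))
        W = rng.uniform(0.2, 3.0, size=(3, 3))
        fit = fit_isotonic_2d(TransformedGrid.from_arrays(Z, W))
        oracle = isotonic_bruteforce(Z, W)
        np.testing.assert_allclose(fit.theta_iso, oracle, atol=1e-6)

    @pytest.mark.parametrize("axis", [0, 1])
    def test_1d_slices_match_weighted_pava(self, axis, rng):
        """Each single-row/column problem reproduces the PAVA solution."""
        n = 7
        z = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        Z = z[None, :] if axis == 0 else z[:, None]
        Wm = w[None, :] if axis == 0 else w[:, None]
        fit = fit_isotonic_2d(TransformedGrid.from_arrays(Z, Wm))
        pava = isotonic_regression(z, weights=w, increasing=False).x
        np.testing.assert_allclose(fit.theta_iso.ravel(), pava, atol=1e-6)

    def test_idempotent_and_scale_equivariant(self, rng):
        Z = rng.normal(size=(4, 5))
        fit = fit_isotonic_2d(tg_from(Z))
        refit = fit_isotonic_2d(tg_from(fit.theta_iso))
        np.testing.assert_allclose(refit.theta_iso, fit.theta_iso, atol=1e-8)
        assert refit.objective == pytest.approx(0.0, abs=1e-10)
        scaled = fit_isotonic_2d(tg_from(3.0 * Z))
        np.testing.assert_allclose(scaled.theta_iso, 3.0 * fit.theta_iso, atol=1e-7)

    def test_surface_is_monotone(self, rng):
        Z = rng.normal(size=(5, 6))
        th = fit_isotonic_2d(tg_from(Z)).theta_iso
        assert np.all(np.diff(th, axis=0) <= 1e-8)
        assert np.all(np.diff(th, axis=1) <= 1e-8)


class TestMonotoneAdditive:
    def test_exact_additive_recovered(self):
        alpha, u, v = 2.0, np.array([0.0, -0.5, -1.0]), np.array([0.0, -0.3, -0.6])
        Z = alpha + u[:, None] + v[None, :]
        fit = fit_monotone_additive(tg_from(Z))
        assert fit.alpha == pytest.approx(alpha, abs=1e-8)
        np.testing.assert_allclose(fit.u, u, atol=1e-8)
        np.testing.assert_allclose(fit.v, v, atol=1e-8)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)

    def test_constant_grid(self):
        fit = fit_monotone_additive(tg_from(np.full((3, 4), 1.7)))
        assert fit.alpha == pytest.approx(1.7, abs=1e-9)
        np.testing.assert_allclose(fit.u, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.v, 0.0, atol=1e-9)
        assert fit.df_null == 1

    def test_2x2_checkerboard_flat_fit(self):
        fit = fit_monotone_additive(tg_from([[1.0, 0.0], [0.0, 1.0]]))
        assert fit.alpha == pytest.approx(0.5, abs=1e-8)
        np.testing.assert_allclose(fit.u, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.v, 0.0, atol=1e-8)
        assert fit.objective == pytest.approx(1.0, abs=1e-8)

    def test_identifiability_and_monotone_constraints(self, rng):
        Z = rng.normal(size=(5, 5))
        fit = fit_monotone_additive(tg_from(Z))
        assert fit.u[0] == 0.0 and fit.v[0] == 0.0
        assert np.all(np.diff(fit.u) <= 1e-12)
        assert np.all(np.diff(fit.v) <= 1e-12)
        # additive-monotone surface is a member of the monotone cone
        assert np.all(np.diff(fit.theta_add, axis=0) <= 1e-12)
        assert np.all(np.diff(fit.theta_add, axis=1) <= 1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_nesting_inequality(self, trial):
        """The additive class is nested in the cone: its objective cannot be smaller."""
        rng = np.random.default_rng(500 + trial)
        Z = rng.normal(size=(4, 4))
        W = rng.uniform(0.5, 2.0, size=(4, 4))
        tg = TransformedGrid.from_arrays(Z, W)
        assert (
            fit_monotone_additive(tg).objective
            >= fit_isotonic_2d(tg).objective - 1e-10
        )

    def test_warns_when_underidentified(self):
        Z = np.full((4, 4), 0.5)
        W = np.zeros((4, 4))
        W[0, :] = 1.0  # 4 cells for 7 parameters
        with pytest.warns(UserWarning, match="additive parameters"):
            fit_monotone_additive(TransformedGrid.from_arrays(Z, W))


class TestEffectiveDf:
    def test_5x5_distinct_levels_gives_9(self):
        u = np.array([0.0, -0.2, -0.5, -0.9, -1.4])
        fit = AdditiveFit(0.0, u, u.copy(), np.zeros((5, 5)), 0.0, 0)
        assert effective_df(fit) == 9

    def test_fully_pooled_gives_1(self):
        fit = AdditiveFit(0.0, np.zeros(4), np.zeros(5), np.zeros((4, 5)), 0.0, 0)
        assert effective_df(fit) == 1

    def test_tied_levels_merged(self):
        u = np.array([0.0, -0.2, -0.2, -0.5])  # 3 distinct
        v = np.array([0.0, -0.1, -0.1, -0.3, -0.3])  # 3 distinct
        fit = AdditiveFit(0.0, u, v, np.zeros((4, 5)), 0.0, 0)
        assert effective_df(fit) == 5

    def test_near_ties_within_tolerance_merged(self):
        u = np.array([0.0, -0.2, -0.2 - 1e-9])
        fit = AdditiveFit(0.0, u, np.zeros(3), np.zeros((3, 3)), 0.0, 0)
        assert effective_df(fit, level_tol=1e-6) == 2


class TestPredictMissing:
    def test_uniform_step_interior_cell_recovered_exactly(self):
        # additive logit surface with uniform steps: envelope midpoint = truth
        a, b = 0.4, 0.7
        theta = 1.0 - a * np.arange(5)[:, None] - b * np.arange(5)[None, :]
        Y = expit(theta)
        g = make_grid(Y)
        truth = Y[2, 3]
        g.Y[2, 3] = np.nan
        g.m[2, 3] = 0
        pred = predict_missing(g)
        assert pred[2, 3] == pytest.approx(truth, abs=1e-7)

    def test_missing_corner_within_envelope(self):
        Y = expit(1.0 - 0.5 * np.arange(3)[:, None] - 0.5 * np.arange(3)[None, :])
        g = make_grid(Y)
        g.Y[2, 2] = np.nan
        g.m[2, 2] = 0
        with pytest.warns(UserWarning, match="one-sided"):
            pred = predict_missing(g)
        # corner has only upper-dose-side... only predecessors: bounded above
        assert pred[2, 2] <= min(Y[1, 2], Y[2, 1]) + 1e-9

    def test_noiseless_holdout_rmse_zero(self):
        theta = 2.0 - 0.3 * np.arange(6)[:, None] - 0.3 * np.arange(6)[None, :]
        Y = expit(theta)
        g = make_grid(Y)
        held = [(1, 2), (3, 3), (4, 1)]
        for i, j in held:
            g.Y[i, j] = np.nan
            g.m[i, j] = 0
        pred = predict_missing(g)
        errs = [pred[i, j] - expit(theta[i, j]) for i, j in held]
        assert np.sqrt(np.mean(np.square(errs))) < 1e-7

    def test_fit_on_observed_cells_unaffected_by_missing(self, additive_grid):
        tg = transform_responses(additive_grid)
        full = fit_isotonic_2d(tg)
        additive_grid.Y[1, 1] = np.nan
        additive_grid.m[1, 1] = 0
        tg2 = transform_responses(additive_grid)
        part = fit_isotonic_2d(tg2)
        obs = ~additive_grid.missing
        np.testing.assert_allclose(part.theta_iso[obs], full.theta_iso[obs], atol=1e-7)
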