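"""Maxent core: optimizer correctness against independent oracles,
normalization, output transforms, and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from maxhab.features import default_beta
from maxhab.model import MaxentModel, fit, regularized_gain

from conftest import toy_matrix


def binary_matrix(m=20, bg_ones=10, bg_zeros=10):
    """Presences all at x=1; background half at 1, half at 0."""
    return toy_matrix(
        {"x": np.ones(m)},
        {"x": np.r_[np.ones(bg_ones), np.zeros(bg_zeros)]},
    )


def oracle_gain(lam_vec, f_pres, f_land, betas):
    """Regularized gain vs uniform, written independently of the fitter."""
    lam_vec = np.atleast_1d(lam_vec)
    term = f_pres.mean(axis=0) @ lam_vec
    lnz = logsumexp(f_land @ lam_vec)
    return term - (lnz - np.log(len(f_land))) - betas @ np.abs(lam_vec)


class TestFitOracle:
    def test_extreme_penalty_full_shrinkage(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1e6, max_iterations=50)
        assert m.k == 0
        assert m.gain == pytest.approx(0.0, abs=1e-12)
        raw = m.predict_raw(fitted_matrix.data.iloc[:100])
        np.testing.assert_allclose(raw, 1.0 / 100, rtol=1e-10)

    def test_binary_feature_matches_1d_grid_search(self):
        mat = binary_matrix()
        model = fit(mat, "L", 1.0, max_iterations=500, tol=1e-10)
        # independent oracle: dense 1-D grid over lambda
        f_pres = mat.presence()[["x"]].to_numpy()
        f_land = mat.data[["x"]].to_numpy()
        beta = np.array(
            [1.0 * default_beta("linear", mat.n_presence)
             * mat.background()["x"].std(ddof=0) / np.sqrt(mat.n_presence)]
        )
        grid = np.linspace(-5, 10, 300_001)
        gains = f_pres.mean() * grid - (
            logsumexp(np.outer(f_land.ravel(), grid), axis=0) - np.log(len(f_land))
        ) - beta[0] * np.abs(grid)
        assert model.gain == pytest.approx(gains.max(), abs=1e-3)
        assert model.lambdas[0] == pytest.approx(grid[np.argmax(gains)], abs=1e-2)

    def test_three_feature_gain_matches_convex_solver(self):
        rng = np.random.default_rng(3)
        mat = toy_matrix(
            {"a": rng.normal(1, 1, 40), "b": rng.normal(0.5, 1, 40), "c": rng.normal(0, 1, 40)},
            {"a": rng.normal(0, 1, 200), "b": rng.normal(0, 1, 200), "c": rng.normal(0, 1, 200)},
        )
        model = fit(mat, "L", 1.0, max_iterations=2000, tol=1e-12)
        f_pres = np.column_stack(
            [np.clip((mat.presence()[v] - mat.data[v].min()) / np.ptp(mat.data[v]), 0, 1)
             for v in "abc"]
        )
        f_land = np.column_stack(
            [np.clip((mat.data[v] - mat.data[v].min()) / np.ptp(mat.data[v]), 0, 1)
             for v in "abc"]
        )
        betas = np.array(
            [default_beta("linear", mat.n_presence)
             * np.std(np.clip((mat.background()[v] - mat.data[v].min()) / np.ptp(mat.data[v]), 0, 1))
             / np.sqrt(mat.n_presence)
             for v in "abc"]
        )
        best = -np.inf
        for start in (np.zeros(3), np.ones(3), -np.ones(3)):
            res = minimize(lambda l: -oracle_gain(l, f_pres, f_land, betas), start,
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000})
            best = max(best, -res.fun)
        assert model.gain == pytest.approx(best, abs=1e-3)

    def test_duplicated_feature_leaves_distribution_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 260)
        single = toy_matrix({"a": x[:60] + 1.0}, {"a": x[60:]})
        doubled = toy_matrix(
            {"a": x[:60] + 1.0, "b": x[:60] + 1.0}, {"a": x[60:], "b": x[60:]}
        )
        m1 = fit(single, "L", 1.0, max_iterations=1000, tol=1e-10)
        m2 = fit(doubled, "L", 1.0, max_iterations=1000, tol=1e-10)
        r1 = m1.predict_raw(single.data)
        r2 = m2.predict_raw(doubled.data)
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_degenerate_matrix_rejected(self):
        mat = toy_matrix({"a": np.full(5, 2.0)}, {"a": np.full(10, 2.0)})
        with pytest.raises(ValueError, match="degenerate"):
            fit(mat, "L", 1.0)


class TestPredictions:
    def test_raw_normalizes_over_evaluation_set(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=200)
        raw = m.predict_raw(fitted_matrix.data)
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)
        assert (raw >= 0).all()

    def test_monotone_feature_gives_monotone_raw(self):
        rng = np.random.default_rng(5)
        mat = toy_matrix({"a": rng.uniform(0.6, 1, 50)}, {"a": rng.uniform(0, 1, 200)})
        m = fit(mat, "L", 0.5, max_iterations=500)
        assert m.lambdas[0] > 0
        xs = pd.DataFrame({"a": np.linspace(0, 1, 20)})
        raw = m.predict_raw(xs)
        assert (np.diff(raw) > 0).all()

    def test_uniform_logistic_is_half_and_cloglog_closed_form(self, fitted_matrix):
        from maxhab.model import _landscape

        m = fit(fitted_matrix, "LQ", 1e6, max_iterations=20)  # all-zero model
        cells = _landscape(fitted_matrix)  # uniform raw 1/N with H = ln N
        assert len(cells) == m.n_landscape
        np.testing.assert_allclose(m.predict_logistic(cells), 0.5, atol=1e-10)
        np.testing.assert_allclose(m.predict_cloglog(cells), 1 - np.exp(-1), atol=1e-10)

    def test_logistic_direct_formula(self):
        """Hand-set entropy ln 4 and raw 0.5 -> e^H p = 2 -> logistic 2/3."""
        f = pd.DataFrame({"a": [0.0]})
        m = MaxentModel(
            features=[], lambdas=np.zeros(0), fc="L", rm=1.0, log_z=0.0,
            entropy=np.log(4), n_presence=1, n_landscape=1, iterations_run=0,
            converged=True, gain=0.0,
        )
        # patch a raw of 0.5 via the un-normalized path: empty feature set
        # gives eta = 0, so raw = exp(0 - log_z); choose log_z = ln 2
        m.log_z = np.log(2)
        raw = m.predict_raw(f, renormalize=False)
        assert raw[0] == pytest.approx(0.5)
        assert m.predict_logistic(f, renormalize=False)[0] == pytest.approx(2 / 3)

    def test_cloglog_dominates_logistic(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=200)
        cells = fitted_matrix.data
        assert (m.predict_cloglog(cells) >= m.predict_logistic(cells) - 1e-12).all()

    def test_entropy_bounded_by_log_cells(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=200)
        assert m.entropy <= np.log(m.n_landscape) + 1e-9


class TestInvariances:
    def test_shrinkage_monotone_in_rm(self, fitted_matrix):
        ks = [fit(fitted_matrix, "LQ", rm, max_iterations=200).k
              for rm in (0.5, 1.0, 2.0, 4.0, 16.0)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_scale_invariance_of_raw_distribution(self, fitted_matrix):
        m1 = fit(fitted_matrix, "LQ", 1.0, max_iterations=300, tol=1e-9)
        scaled = fitted_matrix.data.copy()
        scaled["elev"] = scaled["elev"] * 3.7 + 1000.0
        mat2 = type(fitted_matrix)(scaled, fitted_matrix.is_presence, fitted_matrix.cells)
        m2 = fit(mat2, "LQ", 1.0, max_iterations=300, tol=1e-9)
        np.testing.assert_allclose(
            m1.predict_raw(fitted_matrix.data), m2.predict_raw(scaled), atol=1e-6
        )

    def test_gain_equals_reported_objective(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=300)
        assert regularized_gain(m, fitted_matrix) == pytest.approx(m.gain, abs=1e-9)

    def test_json_round_trip_reprojects(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=100)
        m2 = MaxentModel.from_json(m.to_json())
        cells = fitted_matrix.data.iloc[:50]
        np.testing.assert_allclose(
            m.predict_logistic(cells), m2.predict_logistic(cells), atol=1e-12
        )
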