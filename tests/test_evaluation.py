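"""Tuning, screening, AUC, jackknife, contribution, response curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import maxhab as mh
from maxhab.evaluation import (
    auc,
    auc_grade,
    compute_aicc,
    jackknife,
    percent_contribution,
    replicate_evaluation,
    response_curve,
    select_variables,
    spearman_matrix,
    tune,
)
from maxhab.model import fit

from conftest import toy_matrix


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc_grade(1.0) == "excellent"

    def test_all_ties_give_half(self):
        assert auc([0.3, 0.3], [0.3, 0.3]) == 0.5

    def test_hand_counted_pairs(self):
        # pairs: 0.7>0.5, 0.7>0.3, 0.4<0.5, 0.4>0.3 -> 3/4
        assert auc([0.7, 0.4], [0.5, 0.3]) == 0.75

    @pytest.mark.parametrize(
        "value,grade",
        [(0.95, "excellent"), (0.9, "excellent"), (0.85, "good"), (0.75, "average"),
         (0.6, "poor"), (0.3, "worse than random")],
    )
    def test_grade_bands(self, value, grade):
        assert auc_grade(value) == grade

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=25),
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=25),
    )
    def test_matches_bruteforce_pair_counting(self, pres, bg):
        brute = np.mean(
            [[1.0 if p > b else 0.5 if p == b else 0.0 for b in bg] for p in pres]
        )
        assert auc(pres, bg) == pytest.approx(brute, abs=1e-12)


class TestAICc:
    def test_direct_formula(self):
        # k=2, n=10, lnL=-5 -> 4 + 10 + 12/7
        aicc = 2 * 2 - 2 * (-5) + 2 * 2 * 3 / (10 - 2 - 1)
        assert aicc == pytest.approx(15.714285714285714)

    def test_model_values(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=200)
        lnl, k, aicc = compute_aicc(m, fitted_matrix)
        assert k == m.k
        assert aicc == pytest.approx(2 * k - 2 * lnl + 2 * k * (k + 1) / (m.n_presence - k - 1))

    def test_zero_parameter_model(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1e6, max_iterations=20)
        lnl, k, aicc = compute_aicc(m, fitted_matrix)
        assert k == 0
        assert aicc == pytest.approx(-2 * lnl)

    def test_overparameterized_flagged(self):
        rng = np.random.default_rng(0)
        mat = toy_matrix(
            {"a": rng.normal(1, 1, 5), "b": rng.normal(1, 1, 5), "c": rng.normal(1, 1, 5),
             "d": rng.normal(1, 1, 5), "e": rng.normal(1, 1, 5)},
            {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50), "c": rng.normal(0, 1, 50),
             "d": rng.normal(0, 1, 50), "e": rng.normal(0, 1, 50)},
        )
        m = fit(mat, "LQ", 0.05, max_iterations=500)
        lnl, k, aicc = compute_aicc(m, mat)
        if k >= mat.n_presence - 1:
            assert np.isnan(aicc)


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.linspace(0, 3, 20)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(1.0)

    def test_reversal(self):
        x = np.linspace(0, 3, 20)
        df = pd.DataFrame({"x": x, "y": -x})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(-1.0)

    def test_tie_handling_matches_manual_average_ranks(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5.0], "y": [10, 20, 20, 30, 40.0]})
        # manual: ranks y = [1, 2.5, 2.5, 4, 5]; Pearson of ranks = 0.974679...
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(0.9746794344808963)

    def test_symmetric_unit_diagonal(self, fitted_matrix):
        r = spearman_matrix(fitted_matrix.presence())
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)


class TestSelectVariables:
    def corr(self, entries, names):
        c = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in entries:
            c.loc[a, b] = c.loc[b, a] = r
        return c

    def contrib(self, d):
        return pd.DataFrame(
            {"variable": list(d), "percent_contribution": list(d.values())}
        )

    def test_dominant_variable_kept(self):
        kept, audit = select_variables(
            self.contrib({"a": 40.0, "b": 5.0}), self.corr([("a", "b", 0.9)], ["a", "b"])
        )
        assert kept == ["a"]
        assert any(e["cause"] == "correlation" and e["partner"] == "a" for e in audit)

    def test_uncorrelated_all_pass(self):
        kept, _ = select_variables(
            self.contrib({"a": 40.0, "b": 5.0, "c": 2.0}), self.corr([], ["a", "b", "c"])
        )
        assert set(kept) == {"a", "b", "c"}

    def test_greedy_chain(self):
        # A-B r=0.85, B-C r=0.85, A-C r=0.1, contributions A>C>B -> keep A, C
        kept, _ = select_variables(
            self.contrib({"a": 50.0, "c": 30.0, "b": 10.0}),
            self.corr([("a", "b", 0.85), ("b", "c", 0.85), ("a", "c", 0.1)], ["a", "b", "c"]),
        )
        assert kept == ["a", "c"]

    def test_low_contribution_dropped(self):
        kept, audit = select_variables(
            self.contrib({"a": 40.0, "b": 0.5}), self.corr([], ["a", "b"])
        )
        assert kept == ["a"]
        assert any(e.get("cause") == "low_contribution" for e in audit)


class TestTune:
    def test_grid_cardinality_and_selected_delta(self, fitted_matrix):
        small = fitted_matrix.subset_variables(["elev", "bio12"])
        result = tune(
            small, fcs=("L", "LQ"), rms=(0.5, 1.0, 2.0), hinge_knots=4, threshold_knots=4,
            max_iterations=100,
        )
        assert len(result.table) == 6
        sel = result.table[
            (result.table.fc == result.selected_fc) & (result.table.rm == result.selected_rm)
        ]
        assert sel["delta_aicc"].iloc[0] == 0.0
        assert (result.table[result.table.valid]["delta_aicc"] >= 0).all()

    def test_empty_grid_rejected(self, fitted_matrix):
        with pytest.raises(ValueError):
            tune(fitted_matrix, fcs=(), rms=())

    def test_linear_truth_selects_simple_feature_class(self):
        """Data generated from a pure-linear response should mostly select
        L or LQ over heavily parameterized classes (complexity recovery)."""
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n_bg = 400
            x = rng.uniform(0, 1, n_bg)
            w = np.exp(2.5 * x)
            pres_x = rng.choice(x, size=60, p=w / w.sum())
            mat = toy_matrix({"x": pres_x}, {"x": x})
            res = tune(mat, fcs=("L", "LQ", "LQHPT"), rms=(0.5, 1.0, 2.0),
                       hinge_knots=6, threshold_knots=6, max_iterations=150)
            hits += res.selected_fc in ("L", "LQ")
        assert hits >= 4


class TestContributionJackknife:
    def test_single_variable_gets_all_credit(self):
        rng = np.random.default_rng(1)
        mat = toy_matrix({"a": rng.uniform(0.5, 1, 50)}, {"a": rng.uniform(0, 1, 300)})
        m = fit(mat, "LQ", 1.0, max_iterations=300)
        t = percent_contribution(m)
        assert t["percent_contribution"].sum() == pytest.approx(100.0, abs=0.01)
        assert t["variable"].tolist() == ["a"]

    def test_contributions_sum_to_hundred(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1.0, max_iterations=300)
        t = percent_contribution(m)
        assert t["percent_contribution"].sum() == pytest.approx(100.0, abs=0.01)

    def test_symmetric_design_splits_evenly(self):
        """Two independent, equally informative variables share the credit
        roughly 50/50; averaging over seeds removes sampling noise."""
        shares = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 4000
            a = rng.uniform(0, 1, n)
            b = rng.uniform(0, 1, n)
            w = np.exp(2 * a + 2 * b)
            pick = rng.choice(n, size=600, p=w / w.sum())
            mat = toy_matrix({"a": a[pick], "b": b[pick]}, {"a": a, "b": b})
            m = fit(mat, "L", 1.0, max_iterations=500)
            t = percent_contribution(m).set_index("variable")
            shares.append(t.loc["a", "percent_contribution"])
        assert np.mean(shares) == pytest.approx(50, abs=10)

    def test_no_gain_model_flagged(self, fitted_matrix):
        m = fit(fitted_matrix, "LQ", 1e6, max_iterations=10)
        t = percent_contribution(m)
        assert "no_gain" in t.columns and len(t) == 0

    def test_jackknife_gains_and_nesting(self, fitted_matrix):
        small = fitted_matrix.subset_variables(["elev", "bio12", "hfp"])
        t = jackknife(small, "LQ", 1.0, max_iterations=150)
        assert set(t["variable"]) == {"elev", "bio12", "hfp"}
        # leaving any variable out cannot beat the full model
        assert (t["gain_without"] <= t["gain_full"] + 1e-9).all()

    def test_noise_variable_with_only_gain_near_zero(self, world):
        stack, _, suit = world
        rng_layer = np.random.default_rng(77).normal(0, 1, stack.grid.shape)
        noisy = mh.EnvStack(stack.grid, dict(stack.layers, noise=rng_layer))
        occ = mh.sample_occurrences(noisy, suit, 220, seed=31)
        thinned, _ = mh.thin(occ, noisy.grid, seed=32)
        matrix, _ = mh.make_sample_matrix(noisy, thinned, n_background=800, seed=33)
        only = fit(matrix.subset_variables(["noise"]), "LQ", 1.0, max_iterations=200)
        assert only.gain < 0.05

    def test_single_variable_matrix_jackknife_degenerate(self, fitted_matrix):
        t = jackknife(fitted_matrix.subset_variables(["elev"]), "LQ", 1.0, max_iterations=100)
        assert np.isnan(t["gain_without"].iloc[0])
        assert t["note"].iloc[0] == "no remaining variables"
        assert t["gain_with_only"].iloc[0] == pytest.approx(t["gain_full"].iloc[0])


class TestReplicates:
    def test_cardinality_and_determinism(self, fitted_matrix):
        kw = dict(n_replicates=4, test_fraction=0.25, hinge_knots=4, max_iterations=80)
        a = replicate_evaluation(fitted_matrix, "LQ", 1.0, seed=5, **kw)
        b = replicate_evaluation(fitted_matrix, "LQ", 1.0, seed=5, **kw)
        assert len(a.aucs) == 4
        assert a.aucs == b.aucs

    def test_split_arithmetic(self):
        rng = np.random.default_rng(6)
        mat = toy_matrix({"a": rng.uniform(0.5, 1, 40)}, {"a": rng.uniform(0, 1, 200)})
        res = replicate_evaluation(mat, "L", 1.0, n_replicates=2, test_fraction=0.25,
                                   seed=0, max_iterations=50)
        # 40 presences -> 10 test / 30 train; AUC defined per replicate
        assert len(res.aucs) == 2
        assert all(0 <= a <= 1 for a in res.aucs)

    def test_mean_map_on_stack(self, world, fitted_matrix):
        stack, _, _ = world
        res = replicate_evaluation(fitted_matrix, "LQ", 1.0, n_replicates=3, seed=1,
                                   stack=stack, max_iterations=80)
        assert res.mean_map.shape == stack.grid.shape
        vals = res.mean_map[~np.isnan(res.mean_map)]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestResponseCurve:
    def test_monotone_model_peaks_at_range_maximum(self):
        rng = np.random.default_rng(8)
        mat = toy_matrix({"a": rng.uniform(0.6, 1, 60)}, {"a": rng.uniform(0, 1, 300)})
        m = fit(mat, "L", 0.5, max_iterations=300)
        rc = response_curve(m, mat, "a")
        assert rc.optimum == pytest.approx(mat.presence()["a"].max())

    def test_known_quadratic_optimum_recovered(self):
        """The single-variable response curve finds the generating optimum
        within 10% of the variable's range in most seeds (the estimate is
        stochastic, so a majority-of-seeds check is the right contract)."""
        hits = 0
        for seed in range(5):
            stack, _, suit = mh.default_world(seed=seed, n_rows=50, n_cols=50)
            occ = mh.sample_occurrences(stack, suit, 200, seed=seed + 500)
            thinned, _ = mh.thin(occ, stack.grid, seed=seed)
            matrix, _ = mh.make_sample_matrix(stack, thinned, n_background=800, seed=seed)
            m = fit(matrix, "LQ", 1.0, max_iterations=300)
            rc = response_curve(m, matrix, "elev", mode="single")
            hits += abs(rc.optimum - 3500.0) < 0.1 * np.ptp(matrix.presence()["elev"])
        assert hits >= 4

    def test_everywhere_below_half_reports_empty_interval(self, fitted_matrix):
        # a model whose landscape entropy sits well below ln(Z * anything)
        # keeps the logistic output under 0.5 across the whole curve
        from maxhab.features import FeatureDef
        from maxhab.model import MaxentModel

        lo, hi = float(fitted_matrix.data["hfp"].min()), float(fitted_matrix.data["hfp"].max())
        m = MaxentModel(
            features=[FeatureDef("linear", ("hfp",), ((lo, hi),))],
            lambdas=np.zeros(1), fc="L", rm=1.0, log_z=np.log(4.0), entropy=0.0,
            n_presence=10, n_landscape=4, iterations_run=0, converged=True, gain=0.0,
        )
        rc = response_curve(m, fitted_matrix, "hfp")
        np.testing.assert_allclose(rc.ordinate, 0.25 / 1.25)
        assert rc.suitable_interval is None
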