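"""OOB forest machinery: variance explained, permutation importance,
backward elimination, repeat aggregation."""

import numpy as np
import pytest

from regmut import (
    backward_elimination,
    fit_forest,
    oob_variance_explained,
    permutation_importance,
    run_selection,
)
from regmut import _seeds
from regmut.forest import ImportanceTable, _rank_importances


def brute_force_importance(model, X, y, seed):
    """Independent re-implementation: explicit loops over trees and features,
    explicit permutation draws from the documented sub-seed scheme."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    F = X.shape[1]
    imps = np.zeros(F)
    for t in range(model.n_trees):
        tree = model.trees[t]
        oob = model.oob_masks[t]
        if not oob.any():
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean((yo - tree.predict(Xo)) ** 2)
        for m in range(F):
            perm = _seeds.permutation_rng(seed, t, m).permutation(len(yo))
            Xp = Xo.copy()
            Xp[:, m] = Xo[perm, m]
            imps[m] += np.mean((yo - tree.predict(Xp)) ** 2) - base
    return imps / model.n_trees


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(42)
    W, F = 60, 5
    X = rng.standard_normal((W, F))
    y = 2.0 * X[:, 0] + X[:, 2] + 0.5 * rng.standard_normal(W)
    return X, y


class TestFitForest:
    def test_constant_response_gives_zero_ve(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        with pytest.warns(UserWarning, match="Var\\(y\\) = 0"):
            model = fit_forest(X, np.full(40, 7.0), n_trees=20, seed=0)
            assert oob_variance_explained(model, np.full(40, 7.0)) == 0.0

    def test_noiseless_single_feature_is_well_explained(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        X = x[:, None]
        model = fit_forest(X, x, n_trees=200, seed=1,
                           hyperparams={"max_features": 1})
        assert oob_variance_explained(model, x) > 0.9

    def test_every_window_has_an_oob_tree(self):
        X = np.random.default_rng(2).standard_normal((50, 4))
        y = X[:, 0]
        model = fit_forest(X, y, n_trees=30, seed=2)
        assert model.oob_masks.any(axis=0).all()
        assert np.isfinite(model.oob_predictions).all()

    def test_deterministic_for_fixed_seed(self, small_problem):
        X, y = small_problem
        m1 = fit_forest(X, y, n_trees=15, seed=5)
        m2 = fit_forest(X, y, n_trees=15, seed=5)
        np.testing.assert_array_equal(m1.oob_predictions, m2.oob_predictions)

    def test_constant_feature_warns_but_fits(self):
        X = np.random.default_rng(3).standard_normal((40, 3))
        X[:, 1] = 4.0
        with pytest.warns(UserWarning, match="constant feature"):
            fit_forest(X, X[:, 0], n_trees=10, seed=3)


class TestVarianceExplained:
    def test_perfect_and_mean_predictions(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=10, seed=1)
        model.oob_predictions = y.copy()
        assert oob_variance_explained(model, y) == pytest.approx(1.0)
        model.oob_predictions = np.full_like(y, y.mean())
        assert oob_variance_explained(model, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_sum_oracle(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=25, seed=9)
        ve = oob_variance_explained(model, y)
        mse = sum((yi - pi) ** 2 for yi, pi in zip(y, model.oob_predictions)) / len(y)
        var = sum((yi - y.mean()) ** 2 for yi in y) / len(y)
        assert ve == pytest.approx(1 - mse / var, abs=1e-12)


class TestPermutationImportance:
    def test_matches_brute_force_oracle(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=25, seed=7)
        imp = permutation_importance(model, X, y, seed=13)
        oracle = brute_force_importance(model, X, y, seed=13)
        np.testing.assert_allclose(
            imp.table["importance"].to_numpy(), oracle, atol=1e-12)

    def test_informative_feature_ranks_first(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=50, seed=3)
        imp = permutation_importance(model, X, y)
        assert imp.top(1) == ["f0"]
        assert imp.table.loc[imp.table["feature"] == "f0", "importance"].iloc[0] > 0

    def test_irrelevant_feature_importance_near_zero(self):
        rng = np.random.default_rng(8)
        W = 200
        X = np.column_stack([rng.standard_normal(W), rng.standard_normal(W)])
        y = 3.0 * X[:, 0]
        model = fit_forest(X, y, n_trees=100, seed=8)
        imp = permutation_importance(model, X, y)
        tab = imp.table.set_index("feature")
        assert abs(tab.loc["f1", "importance"]) < 0.05 * tab.loc["f0", "importance"]

    def test_rank_ties_break_lexicographically(self):
        tab = _rank_importances(["b", "a", "c"], np.array([1.0, 1.0, 2.0]))
        t = tab.table.set_index("feature")["rank"]
        assert t["c"] == 1 and t["a"] == 2 and t["b"] == 3


class TestBackwardElimination:
    def test_keep_one_is_single_feature_forest(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=20, seed=1)
        imp = permutation_importance(model, X, y)
        path = backward_elimination(X, y, imp, keep=1, n_trees=20, seed=1)
        assert len(path.steps) == 1
        best = imp.top(1)[0]
        sub = X[:, [int(best[1:])]]
        ref = fit_forest(sub, y, n_trees=20,
                         seed=_seeds.elimination_seed(1, 0))
        assert path.steps[0][1] == pytest.approx(
            oob_variance_explained(ref, y), abs=1e-12)

    def test_step_bookkeeping(self, small_problem):
        X, y = small_problem
        model = fit_forest(X[:, :3], y, n_trees=20, seed=2)
        imp = permutation_importance(model, X[:, :3], y)
        path = backward_elimination(X[:, :3], y, imp, keep=3, n_trees=20, seed=2)
        assert [len(s[0]) for s in path.steps] == [3, 2, 1]
        assert len(path.feature_step_ve) == 3
        assert set(path.removed_order) == {"f0", "f1", "f2"}

    def test_causal_pair_survives_elimination(self):
        """With 2 causal of 10 features the causal pair is the last two
        standing in nearly all seeded runs."""
        hits = 0
        n_runs = 15
        for run in range(n_runs):
            rng = np.random.default_rng(100 + run)
            X = rng.standard_normal((150, 10))
            y = 2 * X[:, 3] + 2 * X[:, 7] + 0.3 * rng.standard_normal(150)
            model = fit_forest(X, y, n_trees=60, seed=run)
            imp = permutation_importance(model, X, y, seed=run)
            path = backward_elimination(X, y, imp, keep=10, n_trees=60, seed=run)
            last_two = {path.removed_order[-1], path.removed_order[-2]}
            hits += last_two == {"f3", "f7"}
        assert hits >= 0.9 * n_runs

    def test_invalid_keep_raises(self, small_problem):
        X, y = small_problem
        model = fit_forest(X, y, n_trees=5, seed=0)
        imp = permutation_importance(model, X, y)
        with pytest.raises(ValueError, match="keep"):
            backward_elimination(X, y, imp, keep=0)


class TestRunSelection:
    def test_min_max_bracket_every_repeat(self):
        rng = np.random.default_rng(55)
        X = rng.standard_normal((80, 4))
        y = X[:, 1] + 0.5 * rng.standard_normal(80)
        summ = run_selection(X, y, n_trees=30, n_repeats=4, keep=4, seed=55)
        assert summ.full_model_ve == pytest.approx(summ.repeat_full_ve.mean())
        for row in summ.per_feature.itertuples():
            if row.n_in_top:
                assert row.step_ve_min <= row.step_ve_mean <= row.step_ve_max
        assert summ.threshold < summ.full_model_ve

    def test_single_repeat_raises(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        with pytest.raises(ValueError, match="n_repeats"):
            run_selection(X, X[:, 0], n_trees=10, n_repeats=1, seed=0)

    def test_determinism_of_summary(self):
        rng = np.random.default_rng(77)
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + rng.standard_normal(60)
        s1 = run_selection(X, y, n_trees=20, n_repeats=3, keep=5, seed=77)
        s2 = run_selection(X, y, n_trees=20, n_repeats=3, keep=5, seed=77)
        assert s1.to_json() == s2.to_json()
        np.testing.assert_array_equal(s1.repeat_full_ve, s2.repeat_full_ve)

    def test_significance_monotone_in_sem(self):
        """Shrinking the SEM raises the threshold and can only remove
        features from the significant set."""
        rng = np.random.default_rng(31)
        X = rng.standard_normal((100, 6))
        y = 2 * X[:, 2] + 0.4 * rng.standard_normal(100)
        summ = run_selection(X, y, n_trees=40, n_repeats=4, keep=6, seed=31)

        def significant(threshold):
            return {
                row.feature for row in summ.per_feature.itertuples()
                if row.n_in_top and row.step_ve_mean >= threshold
                and row.step_ve_mean > 0
            }

        full = summ.full_model_ve
        for frac in (1.0, 0.5, 0.25, 0.0):
            assert significant(full - frac * summ.sem) >= significant(
                full - 0.5 * frac * summ.sem)
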