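"""Feature-selection routes and their recovery of planted signals."""

import numpy as np
import pandas as pd
import pytest

from phenoseg.selection import (SelectionConfig, cars_retention_schedule,
                                cars_select, consensus, lars_select,
                                lasso_select, pearson_screen)


class TestPearsonScreen:
    def test_identical_column_selected_with_r_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=50),
                          "b": rng.normal(size=50)})
        y = X["a"].to_numpy().copy()
        res = pearson_screen(X, y, threshold=0.8)
        assert res.selected[0] == "a"
        assert res.diagnostics["r"]["a"] == pytest.approx(1.0)

    def test_strict_threshold_one_yields_empty_selection(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = X.sum(axis=1).to_numpy() + rng.normal(size=50)
        res = pearson_screen(X, y, threshold=0.999999)
        assert res.selected == []

    def test_planted_table_recovers_exactly_the_informative_set(
            self, planted_table):
        res = pearson_screen(planted_table.features, planted_table.target, 0.8)
        assert set(res.selected) == set(planted_table.informative)

    def test_affine_rescaling_invariance(self, planted_table):
        X = planted_table.features.copy()
        X["B"] = 3.5 * X["B"] - 7.0
        res = pearson_screen(X, planted_table.target, 0.8)
        assert set(res.selected) == set(planted_table.informative)

    def test_zero_variance_column_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=30),
                          "flat": np.ones(30)})
        y = X["a"].to_numpy()
        with pytest.warns(UserWarning, match="flat"):
            res = pearson_screen(X, y, 0.5)
        assert "flat" not in res.selected


class TestLassoSelect:
    def test_planted_recovery_with_few_false_positives(self, planted_table):
        res = lasso_select(planted_table.features, planted_table.target,
                           SelectionConfig(seed=0))
        informative = set(planted_table.informative)
        assert len(informative & set(res.selected)) >= 3
        assert len(set(res.selected) - informative) <= 2

    def test_huge_lambda_empty_and_tiny_lambda_full_support(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        beta = np.array([1.0, -2.0, 0.5, 1.5])
        y = X.to_numpy() @ beta + 0.01 * rng.normal(size=60)
        from sklearn.linear_model import Lasso

        Xs = (X - X.mean()) / X.std(ddof=0)
        yc = y - y.mean()
        lam_max = np.max(np.abs(Xs.to_numpy().T @ yc)) / len(yc)
        full = Lasso(alpha=lam_max * 1e-6).fit(Xs, yc)
        empty = Lasso(alpha=lam_max * 1.01).fit(Xs, yc)
        assert (np.abs(full.coef_) > 1e-8).all()
        assert (np.abs(empty.coef_) < 1e-10).all()

    def test_selection_agrees_with_independent_l1_solver(self, planted_table):
        """Refit at the chosen lambda with sklearn's coordinate descent from
        a cold start and compare supports."""
        from sklearn.linear_model import Lasso

        res = lasso_select(planted_table.features, planted_table.target,
                           SelectionConfig(seed=0))
        X = planted_table.features.to_numpy()
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        y = planted_table.target - planted_table.target.mean()
        refit = Lasso(alpha=res.diagnostics["alpha"], max_iter=100_000,
                      tol=1e-10).fit(Xs, y)
        support = {planted_table.features.columns[j]
                   for j in np.nonzero(np.abs(refit.coef_) > 1e-8)[0]}
        assert support == set(res.selected)

    def test_degenerate_response_rejected(self, planted_table):
        with pytest.raises(ValueError, match="variance"):
            lasso_select(planted_table.features,
                         np.zeros(len(planted_table.features)))


class TestLarsSelect:
    def test_first_entry_is_max_absolute_correlation(self, planted_table):
        X, y = planted_table.features, planted_table.target
        res = lars_select(X, y, k=1)
        rs = {c: abs(np.corrcoef(X[c], y)[0, 1]) for c in X.columns}
        assert res.selected == [max(rs, key=rs.get)]

    def test_k_zero_gives_empty_selection(self, planted_table):
        res = lars_select(planted_table.features, planted_table.target, k=0)
        assert res.selected == []

    def test_orthogonal_design_entry_order_and_path(self):
        """On a zero-mean orthogonal ±1 (Walsh) design the LARS entry order
        follows the absolute correlations and every path breakpoint matches
        the soft-thresholding closed form for orthogonal regressors."""
        n = 64
        idx = np.arange(n)
        X = np.stack([np.where(idx & bit, 1.0, -1.0)
                      for bit in (32, 16, 8)], axis=1)
        assert np.allclose(X.T @ X, n * np.eye(3))   # orthogonal, zero-mean
        coefs = np.array([0.9, 0.5, 0.1])
        y = X @ coefs
        frame = pd.DataFrame(X, columns=["hi", "mid", "lo"])
        res = lars_select(frame, y, k=3)
        assert res.selected == ["hi", "mid", "lo"]
        # knots occur when the shared correlation level reaches the next
        # |coefficient|; active coefs are soft-thresholded at that level
        path = np.asarray(res.diagnostics["coef_path"])
        expected = np.array([
            [0.0, 0.4, 0.8, 0.9],
            [0.0, 0.0, 0.4, 0.5],
            [0.0, 0.0, 0.0, 0.1],
        ])
        np.testing.assert_allclose(path, expected, atol=1e-10)

    def test_planted_recovery(self, planted_table):
        res = lars_select(planted_table.features, planted_table.target, k=4)
        informative = set(planted_table.informative)
        assert len(informative & set(res.selected)) >= 3
        assert len(set(res.selected) - informative) <= 2


class TestCarsSelect:
    def test_retention_schedule_closed_form(self):
        for p, n in ((30, 50), (10, 20), (100, 50)):
            sched = cars_retention_schedule(p, n)
            assert sched[0] == pytest.approx(1.0, rel=1e-12)
            assert sched[-1] == pytest.approx(2 / p, rel=1e-12)
            assert (np.diff(sched) < 0).all()
            k = np.log(p / 2) / (n - 1)
            a = (p / 2) ** (1 / (n - 1))
            np.testing.assert_allclose(
                sched, a * np.exp(-k * np.arange(1, n + 1)), rtol=1e-12)

    def test_two_features_final_set_nonempty_subset(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        y = (X["a"] + X["b"]).to_numpy() + 0.1 * rng.normal(size=40)
        res = cars_select(X, y, SelectionConfig(cars_runs=10, seed=1))
        assert 1 <= len(res.selected) <= 2
        assert set(res.selected) <= {"a", "b"}

    def test_planted_recovery_and_noise_exclusion(self, planted_table):
        res = cars_select(planted_table.features, planted_table.target,
                          SelectionConfig(seed=0))
        informative = set(planted_table.informative)
        assert len(informative & set(res.selected)) >= 3
        assert len(set(res.selected) - informative) <= 2
        best_run = res.diagnostics["best_run"]
        entry = next(h for h in res.diagnostics["history"]
                     if h["run"] == best_run)
        noise_kept = [f for f in entry["retained"] if f not in informative]
        assert 26 - len(noise_kept) >= 20

    def test_seed_determinism(self, planted_table):
        a = cars_select(planted_table.features, planted_table.target,
                        SelectionConfig(seed=3))
        b = cars_select(planted_table.features, planted_table.target,
                        SelectionConfig(seed=3))
        assert a.selected == b.selected


class TestConsensus:
    def test_identical_selections_form_core(self):
        from phenoseg.selection import SelectionResult

        r1 = SelectionResult("m1", ["a", "b"])
        r2 = SelectionResult("m2", ["b", "a"])
        out = consensus([r1, r2])
        assert out["core_set"] == ["a", "b"]

    def test_disjoint_selections_empty_core(self):
        from phenoseg.selection import SelectionResult

        out = consensus([SelectionResult("m1", ["a"]),
                         SelectionResult("m2", ["b"])])
        assert out["core_set"] == []
        assert out["frequency"] == {"a": 1, "b": 1}

    def test_full_pipeline_consensus_contains_common_recoveries(
            self, planted_table):
        X, y = planted_table.features, planted_table.target
        cfg = SelectionConfig(seed=0)
        results = [pearson_screen(X, y, 0.8),
                   lasso_select(X, y, cfg),
                   lars_select(X, y, k=4),
                   cars_select(X, y, cfg)]
        out = consensus(results)
        common = set.intersection(*(set(r.selected) for r in results))
        assert set(out["core_set"]) == common
        assert common & set(planted_table.informative)

    def test_column_order_invariance(self, planted_table):
        X, y = planted_table.features, planted_table.target
        shuffled = X[list(X.columns[::-1])]
        a = pearson_screen(X, y, 0.8)
        b = pearson_screen(shuffled, y, 0.8)
        assert set(a.selected) == set(b.selected)
        la = lasso_select(X, y, SelectionConfig(seed=0))
        lb = lasso_select(shuffled, y, SelectionConfig(seed=0))
        assert set(la.selected) == set(lb.selected)
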