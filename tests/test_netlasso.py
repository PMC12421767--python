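import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso

import saltnet as sn
from saltnet.netlasso import (
    DEFAULT_LAMBDA_GRID,
    DecisionConfig,
    DecisionModelResult,
    RepeatRecord,
    _cd_path,
    _cd_path_py,
    assemble_network,
    classify_and_select,
    cv_select_lambda,
    decision_loop,
    kkt_violation,
    lasso_objective,
    metabolite_rng,
    one_se_lambda,
    pcc_prefilter,
    solve_lasso,
)


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestPrefilter:
    def test_identical_vector_has_unit_correlation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame([y], index=["g0"])
        kept = pcc_prefilter(expr, y)
        assert kept["g0"] == pytest.approx(1.0)

    def test_hand_covariance_arithmetic(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"])
        kept = pcc_prefilter(expr, np.array([1.0, 2.0, 4.0]))
        assert kept["g0"] == pytest.approx(0.9819805, abs=1e-6)

    def test_constant_gene_excluded(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["c", "g"])
        kept = pcc_prefilter(expr, np.array([1.0, 2.0, 3.0]))
        assert list(kept.index) == ["g"]

    def test_signed_default_drops_negative_regulators(self):
        expr = pd.DataFrame([[3.0, 2.0, 1.0]], index=["g0"])
        y = np.array([1.0, 2.0, 3.0])
        assert pcc_prefilter(expr, y).empty
        assert list(pcc_prefilter(expr, y, absolute=True).index) == ["g0"]

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g0"])
        with pytest.raises(sn.SaltnetError, match="3 samples"):
            pcc_prefilter(expr, np.array([1.0, 2.0]))


class TestSolveLasso:
    def test_penalty_above_max_correlation_zeroes_solution(self):
        rng = np.random.default_rng(0)
        X = _standardize(rng.normal(size=(40, 5)))
        y = rng.normal(size=40)
        y -= y.mean()
        lam_max = np.abs(X.T @ y).max() / 40
        beta = solve_lasso(X, y, lam_max * 1.0001)
        np.testing.assert_array_equal(beta, 0.0)

    def test_single_predictor_soft_threshold(self):
        # OLS slope 2, lambda 0.5 -> soft(2, 0.5) = 1.5
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x
        beta = solve_lasso(x[:, None], y, 0.5)
        assert beta[0] == pytest.approx(1.5, abs=1e-8)

    def test_orthonormal_design_closed_form(self):
        rng = np.random.default_rng(2)
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q * np.sqrt(n)  # X'X/n = I
        beta_true = rng.normal(size=p)
        y = X @ beta_true + 0.1 * rng.normal(size=n)
        ols = X.T @ y / n
        for lam in (0.05, 0.3, 1.0):
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(solve_lasso(X, y, lam), expected, atol=1e-8)

    def test_matches_sklearn_on_correlated_designs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, p = 50, 7
            base = rng.normal(size=(n, 3))
            X = _standardize(base @ rng.normal(size=(3, p)) + rng.normal(size=(n, p)))
            y = rng.normal(size=n)
            y -= y.mean()
            lam = float(rng.uniform(0.02, 0.5))
            mine = solve_lasso(X, y, lam)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=100000).fit(X, y).coef_
            np.testing.assert_allclose(mine, ref, atol=1e-6)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_kkt_conditions_hold(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 30, 6
        X = _standardize(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        y -= y.mean()
        lam = float(rng.uniform(0.01, 1.0))
        beta = solve_lasso(X, y, lam)
        assert kkt_violation(X, y, beta, lam) < 1e-6

    def test_objective_non_increasing_with_sweep_budget(self):
        rng = np.random.default_rng(9)
        n, p = 40, 8
        X = _standardize(rng.normal(size=(n, p)) @ np.diag(rng.uniform(0.5, 2, p)))
        y = rng.normal(size=n)
        y -= y.mean()
        G, b = X.T @ X / n, X.T @ y / n
        lam = 0.05
        objs = []
        for budget in (1, 2, 3, 5, 10, 50):
            beta = _cd_path_py(G, b, np.array([lam]), tol=0.0, max_sweeps=budget)[0]
            objs.append(lasso_objective(X, y, beta, lam))
        assert np.all(np.diff(objs) <= 1e-12)

    def test_compiled_and_python_paths_agree(self):
        rng = np.random.default_rng(14)
        n, p = 35, 6
        X = _standardize(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        y -= y.mean()
        G, b = X.T @ X / n, X.T @ y / n
        lams = np.array([0.5, 0.2, 0.05, 0.01])
        np.testing.assert_allclose(
            _cd_path(G, b, lams),
            _cd_path_py(G, b, lams, tol=1e-10, max_sweeps=100000),
            atol=1e-9,
        )

    def test_non_finite_input_rejected(self):
        with pytest.raises(sn.SaltnetError, match="non-finite"):
            solve_lasso(np.array([[np.nan]]), np.array([1.0]), 0.1)


class TestLambdaSelection:
    def test_grid_has_one_hundred_values(self):
        assert len(DEFAULT_LAMBDA_GRID) == 100
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(0.01)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(1.0)

    def test_one_se_rule_on_constructed_curve(self):
        grid = np.array([0.1, 0.2, 0.3, 0.4])
        mean = np.array([1.0, 0.5, 0.45, 0.6])
        se = np.array([0.1, 0.1, 0.05, 0.1])
        # band = 0.45 + 0.05 = 0.50; largest lambda with mean <= 0.50 is 0.3
        assert one_se_lambda(grid, mean, se) == pytest.approx(0.3)

    def test_pure_noise_selects_strongest_penalty(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        lam, curve = cv_select_lambda(X, y, rng=np.random.default_rng(6))
        assert lam == pytest.approx(1.0)
        assert len(curve) == 100

    def test_strong_signal_selects_weaker_penalty(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + 0.05 * rng.normal(size=60)
        lam, _ = cv_select_lambda(X, y, rng=np.random.default_rng(8))
        assert lam < 0.5

    def test_fold_reduction_warns_for_tiny_n(self, caplog):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with caplog.at_level("WARNING", logger="saltnet.netlasso"):
            cv_select_lambda(X, y, n_folds=10, rng=np.random.default_rng(1))
        assert any("reducing folds" in r.message for r in caplog.records)


class TestDecisionLoop:
    def _expr(self, rng, n_genes=30, n=40):
        return pd.DataFrame(
            rng.normal(size=(n_genes, n)),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n)],
        )

    def test_exact_copy_gene_always_selected(self):
        rng = np.random.default_rng(11)
        expr = self._expr(rng)
        y = expr.loc["g005"].to_numpy().copy()
        cfg = DecisionConfig(n_repeats=20, seed=1)
        res = decision_loop(expr, y, "met", cfg, np.random.default_rng(2))
        assert res.status == "predictable"
        assert res.mean_r == pytest.approx(1.0, abs=1e-9)
        assert res.n_valid == 20
        assert res.gene_frequency["g005"] == 1.0

    def test_unrelated_noise_is_non_modelable(self):
        rng = np.random.default_rng(12)
        expr = self._expr(rng)
        y = rng.normal(size=expr.shape[1])
        res = decision_loop(
            expr, y, "met", DecisionConfig(n_repeats=10), np.random.default_rng(3)
        )
        assert res.status == "non-modelable"
        assert res.repeats == ()

    def test_planted_regulators_recovered(self, small_dataset):
        from saltnet.pipeline import expression_for_network

        ds = small_dataset
        expr = expression_for_network(ds.tpm)
        met = ds.metabolites.metabolites[0]
        truth = {g for g, m, _ in ds.truth.regulatory_edges if m == met}
        cfg = DecisionConfig(seed=9)
        res = decision_loop(
            expr, ds.metabolites.data.loc[met].to_numpy(), met, cfg,
            metabolite_rng(9, met),
        )
        assert res.status == "predictable"
        assert res.mean_r > 0.8
        selected = {g for g, f in res.gene_frequency.items() if f > 0.5}
        assert truth <= selected

    def test_small_test_split_rejected(self):
        rng = np.random.default_rng(13)
        expr = self._expr(rng, n=10)
        y = expr.loc["g001"].to_numpy()
        with pytest.raises(sn.SaltnetError, match="more samples"):
            decision_loop(expr, y, "met", DecisionConfig(), np.random.default_rng(1))

    def test_identical_seed_gives_identical_results(self):
        rng = np.random.default_rng(14)
        expr = self._expr(rng)
        y = expr.loc["g002"].to_numpy() + 0.3 * rng.normal(size=expr.shape[1])
        cfg = DecisionConfig(n_repeats=10, seed=4)
        r1 = decision_loop(expr, y, "met", cfg, metabolite_rng(4, "met"))
        r2 = decision_loop(expr, y, "met", cfg, metabolite_rng(4, "met"))
        assert r1 == r2


class TestClassifyAndAssemble:
    def _result(self, met, mean_r, freq):
        valid = 10
        repeats = []
        for i in range(valid):
            sel = ("gA",) if i < round(freq * valid) else ()
            repeats.append(RepeatRecord(sel, 0.1, mean_r, True))
        status = "predictable" if mean_r > 0.8 else "unpredictable"
        return DecisionModelResult(met, ("gA",), tuple(repeats), status)

    def test_mean_r_exactly_at_threshold_not_predictable(self):
        res = self._result("m1", 0.8, 1.0)
        pred, regs = classify_and_select([res], DecisionConfig())
        assert pred == set()

    def test_frequency_exactly_half_not_a_regulator(self):
        res = self._result("m1", 0.9, 0.5)
        pred, regs = classify_and_select([res], DecisionConfig())
        assert pred == {"m1"}
        assert regs["m1"] == {}

    def test_empty_results_give_empty_network(self):
        pred, regs = classify_and_select([], DecisionConfig())
        net = assemble_network(regs, [])
        assert pred == set() and net.edges == ()

    def test_hand_enumerated_edges_and_hub_boundary(self):
        results = [
            DecisionModelResult(f"m{i}", ("g1", "g2"), (), "predictable")
            for i in range(5)
        ]
        regulators = {f"m{i}": {"g1": 0.9} for i in range(5)}
        regulators["m0"]["g2"] = 0.7

        # mean_r property needs valid repeats; patch via identical records
        results = [
            DecisionModelResult(
                r.metabolite, r.candidate_genes,
                (RepeatRecord(("g1",), 0.1, 0.95, True),), "predictable",
            )
            for r in results
        ]
        net = assemble_network(regulators, results, hub_degree=5)
        assert net.edge_set == {("g1", f"m{i}") for i in range(5)} | {("g2", "m0")}
        assert net.hubs == ["g1"]  # 5 metabolites -> hub; g2 with 1 -> not

    def test_vip_restriction_drops_non_salt_responsive(self):
        results = [
            DecisionModelResult(
                m, ("gA",), (RepeatRecord(("gA",), 0.1, 0.9, True),), "predictable"
            )
            for m in ("m1", "m2")
        ]
        regulators = {"m1": {"gA": 0.8}, "m2": {"gA": 0.8}}
        vip = pd.Series({"m1": 1.4, "m2": 0.3})
        net = assemble_network(regulators, results, vip_stress=vip)
        assert net.edge_set == {("gA", "m1")}
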