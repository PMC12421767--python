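import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import saltnet as sn
from saltnet.diffexpr import (
    _fit_gene,
    bh_adjust,
    build_design,
    estimate_dispersion,
    estimate_size_factors,
    filter_expressed,
    nb_loglik,
)
from tests.conftest import bh_stepup_oracle


def _sheet(n_treat=2, n_times=2, n_reps=3, n_batches=None):
    n_batches = n_batches or n_reps
    rows = []
    for ti, t in enumerate([f"t{i}" for i in range(n_times)]):
        for treat in ["control", "salt"][:n_treat]:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{treat}_{t}_r{rep}",
                        "ecotype": "E",
                        "treatment": treat,
                        "time": t,
                        "batch": f"b{(rep - 1) % n_batches + 1}",
                    }
                )
    return sn.SampleSheet(pd.DataFrame(rows))


def _counts(sheet, values):
    return sn.CountMatrix(
        pd.DataFrame(
            np.atleast_2d(values),
            index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
            columns=sheet.sample_ids,
        )
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, tiny_sheet):
        mat = _counts(tiny_sheet, [[5, 5, 5, 5], [9, 9, 9, 9]])
        np.testing.assert_allclose(estimate_size_factors(mat), np.ones(4))

    def test_two_sample_closed_form(self):
        # ratios to the geometric-mean reference: 1/sqrt(2) and sqrt(2)
        mat = sn.CountMatrix(
            pd.DataFrame([[100, 200], [50, 100]], index=["a", "b"], columns=["s1", "s2"])
        )
        np.testing.assert_allclose(
            estimate_size_factors(mat), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(42)
        k = rng.integers(1, 500, size=(50, 6))
        mat = sn.CountMatrix(
            pd.DataFrame(k, index=[f"g{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(6)])
        )
        ref = np.exp(np.log(k).mean(axis=1))  # geometric mean per gene
        expected = np.median(k / ref[:, None], axis=0)
        np.testing.assert_allclose(estimate_size_factors(mat), expected, rtol=1e-12)

    def test_no_all_positive_gene_suggests_fallback(self, tiny_sheet):
        mat = _counts(tiny_sheet, [[0, 5, 5, 5], [9, 0, 9, 9]])
        with pytest.raises(sn.SaltnetError, match="pseudo_reference"):
            estimate_size_factors(mat)
        assert np.all(estimate_size_factors(mat, pseudo_reference=True) > 0)


class TestNbLikelihood:
    def test_closed_form_at_zero_count(self):
        # P(0) = (1 + alpha*mu)^(-1/alpha) = 1/2 at mu=1, alpha=1
        assert nb_loglik(np.array([0.0]), np.array([1.0]), 1.0) == pytest.approx(
            -np.log(2), abs=1e-10
        )

    def test_poisson_limit(self):
        y = np.array([0.0, 3.0, 10.0])
        mu = np.array([1.0, 4.0, 9.0])
        pois = np.sum(y * np.log(mu) - mu - [0.0, np.log(6.0), np.log(3628800.0)])
        assert nb_loglik(y, mu, 1e-8) == pytest.approx(pois, abs=1e-6)

    def test_intercept_only_fit_matches_grid_search(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(30, size=8).astype(float)
        sf = rng.uniform(0.5, 2.0, size=8)
        X = np.ones((8, 1))
        fit = _fit_gene(y, X, np.log(sf), alpha=0.3)
        grid = np.linspace(np.log(1.0), np.log(100.0), 20001)
        lls = [nb_loglik(y, np.exp(b) * sf, 0.3) for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        assert fit.loglik >= max(lls) - 1e-6


class TestDispersion:
    def test_poisson_data_gives_near_zero_alpha(self):
        sheet = _sheet(n_times=2, n_reps=3)  # n = 12
        rng = np.random.default_rng(8)
        k = rng.poisson(100, size=(200, sheet.n_samples))
        mat = _counts(sheet, k)
        design = build_design(sheet)
        alphas = estimate_dispersion(
            mat, sheet, design, np.ones(sheet.n_samples), shrink=False
        )
        assert np.median(alphas) < 0.01

    def test_nb_alpha_recovered_within_band(self):
        sheet = _sheet(n_times=5, n_reps=5)  # n = 50
        rng = np.random.default_rng(9)
        mu, alpha = 50.0, 0.5
        k = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=(200, sheet.n_samples)))
        mat = _counts(sheet, k)
        design = build_design(sheet)
        alphas = estimate_dispersion(
            mat, sheet, design, np.ones(sheet.n_samples), shrink=False
        )
        assert 0.35 < np.median(alphas) < 0.65

    def test_all_zero_gene_rejected(self):
        sheet = _sheet()
        mat = _counts(sheet, np.vstack([np.zeros(sheet.n_samples, dtype=int),
                                        np.full(sheet.n_samples, 7)]))
        with pytest.raises(sn.SaltnetError, match="all-zero"):
            estimate_dispersion(mat, sheet, build_design(sheet), np.ones(sheet.n_samples))


class TestDesign:
    def test_interaction_df_for_14_times_3_batches(self):
        sheet = _sheet(n_times=14, n_reps=3, n_batches=3)
        full = build_design(sheet, interaction=True)
        reduced = build_design(sheet, interaction=False)
        assert full.rank - reduced.rank == 13
        assert len(full.interaction_cols) == 13

    def test_rank_deficient_design_reports_aliased(self):
        # single treatment level is rejected upstream; force aliasing via
        # a time level that never occurs with salt
        rows = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "ecotype": ["E"] * 6,
                "treatment": ["control", "control", "control", "control", "salt", "salt"],
                "time": ["t0", "t1", "t2", "t2", "t0", "t0"],
                "batch": ["b1"] * 6,
            }
        )
        sheet = sn.SampleSheet(rows)
        with pytest.raises(sn.SaltnetError, match="aliased"):
            build_design(sheet, interaction=True).require_full_rank()


class TestLrt:
    def test_constant_gene_has_zero_stat_unit_pvalue(self):
        sheet = _sheet(n_times=3, n_reps=2)
        mat = _counts(sheet, np.full((1, sheet.n_samples), 50))
        res = sn.lrt_sset(
            mat, sheet, size_factors=np.ones(sheet.n_samples), dispersion=np.array([0.1])
        )
        assert res.lrt_stat[0] == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue[0] > 0.999

    def test_stat_invariant_to_factor_level_order(self):
        sheet = _sheet(n_times=3, n_reps=2)
        rng = np.random.default_rng(12)
        k = rng.poisson(80, size=(5, sheet.n_samples))
        mat = _counts(sheet, k)
        disp = np.full(5, 0.2)
        sf = np.ones(sheet.n_samples)
        res1 = sn.lrt_sset(mat, sheet, size_factors=sf, dispersion=disp)

        tbl = sheet.table.copy()
        tbl["time"] = tbl["time"].cat.reorder_categories(["t2", "t0", "t1"])
        tbl["treatment"] = tbl["treatment"].cat.reorder_categories(["salt", "control"])
        sheet2 = sn.SampleSheet(tbl, baseline_time="t2")
        res2 = sn.lrt_sset(mat, sheet2, size_factors=sf, dispersion=disp)
        np.testing.assert_allclose(res1.lrt_stat, res2.lrt_stat, atol=1e-6)

    def test_all_zero_genes_skipped_and_reported(self):
        sheet = _sheet(n_times=2, n_reps=2)
        k = np.vstack([np.zeros(sheet.n_samples, int), np.full(sheet.n_samples, 30)])
        res = sn.lrt_sset(
            _counts(sheet, k), sheet,
            size_factors=np.ones(sheet.n_samples), dispersion=np.array([0.1]),
        )
        assert res.attrs["skipped"] == ["g0"]
        assert list(res.gene) == ["g1"]


class TestWald:
    def test_constant_gene_contrast_is_null(self):
        sheet = _sheet(n_times=3, n_reps=2)
        mat = _counts(sheet, np.full((1, sheet.n_samples), 40))
        res = sn.wald_deat(
            mat, sheet, size_factors=np.ones(sheet.n_samples), dispersion=np.array([0.05])
        )
        assert np.all(np.abs(res.wald_stat) < 1e-3)
        assert np.all(res.pvalue > 0.99)
        assert not res.is_deat.any()

    def test_recovers_planted_salt_doubling(self):
        sheet = _sheet(n_times=2, n_reps=6)  # 6 per cell
        rng = np.random.default_rng(15)
        mu = np.full(sheet.n_samples, 200.0)
        salt_t1 = (
            (sheet.table["treatment"] == "salt") & (sheet.table["time"] == "t1")
        ).to_numpy()
        mu[salt_t1] *= 2.0
        k = rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu))
        res = sn.wald_deat(
            _counts(sheet, k), sheet,
            size_factors=np.ones(sheet.n_samples), dispersion=np.array([0.05]),
        )
        row = res[(res.time == "t1")].iloc[0]
        assert 0.7 <= row.log2fc <= 1.3
        baseline = res[(res.time == "t0")].iloc[0]
        assert abs(baseline.log2fc) < 0.5

    def test_deat_flag_consistent_with_thresholds(self, small_dataset):
        res = sn.wald_deat(
            small_dataset.counts.subset_features(small_dataset.counts.genes[:15]),
            small_dataset.sheet,
            size_factors=np.ones(small_dataset.sheet.n_samples),
            dispersion=np.full(15, 0.2),
        )
        expected = (res.fdr < 0.05) & (res.log2fc.abs() >= 1.0)
        assert (res.is_deat == expected.fillna(False)).all()


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_nan_passthrough_and_range_check(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(sn.SaltnetError):
            bh_adjust([1.5])


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(1.0, ["g1"]), (0.0, ["g0", "g1"])],
    )
    def test_threshold_is_inclusive(self, threshold, expected):
        tpm = sn.TpmMatrix(
            pd.DataFrame(
                [[0.0, 0.0], [1.0, 1.0]], index=["g0", "g1"], columns=["s1", "s2"]
            )
        )
        assert filter_expressed(tpm, threshold) == expected
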