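"""Differential expression: model fits, Fs shrinkage, permutation p-values,
FDR adjustment and fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from toxsetpipe.diffexpr import (
    differential_expression,
    f1_test,
    f_statistic,
    fdr_adjust,
    fit_gene_models,
    fold_change_lsmeans,
    fs_statistic,
    permutation_pvalues,
)


def _matrix_design(values, make_matrix, make_design, n_per_group):
    x = make_matrix(
        values,
        samples=[f"c{i + 1}" for i in range(n_per_group)]
        + [f"t{i + 1}" for i in range(n_per_group)],
    )
    return x, make_design(n_per_group)


class TestFitGeneModels:
    def test_constant_gene_has_zero_treatment_ss(self, make_matrix, make_design):
        x, design = _matrix_design([[3.0] * 8], make_matrix, make_design, 4)
        fits = fit_gene_models(x, design)
        assert fits.ss_treatment.iloc[0] == 0.0
        assert f_statistic(fits).iloc[0] == 0.0  # F undefined-as-zero

    def test_pure_shift_zero_residual(self, make_matrix, make_design):
        x, design = _matrix_design([[0.0, 0.0, 1.0, 1.0]], make_matrix, make_design, 2)
        fits = fit_gene_models(x, design)
        assert fits.lsmean_treated.iloc[0] - fits.lsmean_control.iloc[0] == 1.0
        assert fits.ms_residual.iloc[0] == 0.0

    def test_matches_oneway_anova_oracle(self, make_matrix, make_design):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((20, 8))
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        fits = fit_gene_models(x, design)
        for i in range(20):
            a, b = values[i, :4], values[i, 4:]
            grand = values[i].mean()
            ss_treat = 4 * (a.mean() - grand) ** 2 + 4 * (b.mean() - grand) ** 2
            sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            assert fits.ss_treatment.iloc[i] == pytest.approx(ss_treat, rel=1e-10)
            assert fits.ms_residual.iloc[i] == pytest.approx(sse / 6, rel=1e-10)
            assert f_statistic(fits).iloc[i] == pytest.approx(
                stats.f_oneway(a, b).statistic, rel=1e-9
            )

    def test_gene_without_residual_df_reported_missing(self, make_matrix, make_design):
        values = np.ones((2, 8))
        values[0, :5] = np.nan  # leaves groups of 3 treated / 0-1 control
        values[0, 5] = np.nan
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        fits = fit_gene_models(x, design)
        assert np.isnan(fits.ms_residual.iloc[0])
        assert np.isfinite(fits.ms_residual.iloc[1])


class TestFsStatistic:
    def test_single_gene_equals_ordinary_f(self, make_matrix, make_design):
        rng = np.random.default_rng(1)
        x, design = _matrix_design(
            rng.standard_normal((1, 8)), make_matrix, make_design, 4
        )
        fits = fit_gene_models(x, design)
        assert fs_statistic(fits).iloc[0] == pytest.approx(
            f_statistic(fits).iloc[0], rel=1e-12
        )

    def test_equal_variances_reduce_to_ordinary_f(self, make_matrix, make_design):
        """When every gene shares the same residual variance the shrinkage
        centre equals each variance and Fs must reproduce F exactly."""
        rng = np.random.default_rng(2)
        resid = rng.standard_normal(8)
        resid[:4] -= resid[:4].mean()
        resid[4:] -= resid[4:].mean()
        values = rng.standard_normal(30)[:, None] + resid[None, :]
        values[:, 4:] += rng.standard_normal(30)[:, None]  # arbitrary shifts
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        fits = fit_gene_models(x, design)
        np.testing.assert_allclose(
            fs_statistic(fits).to_numpy(),
            f_statistic(fits).to_numpy(),
            rtol=1e-10,
        )

    def test_shrinkage_contracts_variance_spread(self, make_matrix, make_design):
        rng = np.random.default_rng(3)
        sigma = np.sqrt(5 * 0.05 / rng.chisquare(5, size=200))
        values = sigma[:, None] * rng.standard_normal((200, 8))
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        fits = fit_gene_models(x, design)
        from toxsetpipe.diffexpr import _shrunk_variances

        raw = fits.ms_residual.to_numpy()
        shrunk = _shrunk_variances(raw, fits.df_residual.to_numpy())
        assert np.var(np.log(shrunk)) < np.var(np.log(raw))

    def test_degenerate_all_zero_variance_rejected(self, make_matrix, make_design):
        x, design = _matrix_design(
            np.tile([[0.0, 0.0, 1.0, 1.0]], (3, 1)), make_matrix, make_design, 2
        )
        fits = fit_gene_models(x, design)
        with pytest.raises(ValueError):
            fs_statistic(fits)


class TestPermutationPvalues:
    def test_minimum_p_is_add_one(self, make_matrix, make_design):
        # with 10 samples per group the exact extreme split is essentially
        # never redrawn, so the observed statistic beats every permutation
        rng = np.random.default_rng(4)
        values = 0.05 * rng.standard_normal((50, 20))
        values[0, 10:] += 50.0
        x, design = _matrix_design(values, make_matrix, make_design, 10)
        fits = fit_gene_models(x, design)
        p = permutation_pvalues(fits, "fs", n_perm=200, seed=1)
        assert p.iloc[0] == pytest.approx(1.0 / 201.0)

    def test_seed_reproducibility(self, make_matrix, make_design):
        rng = np.random.default_rng(5)
        x, design = _matrix_design(
            rng.standard_normal((30, 8)), make_matrix, make_design, 4
        )
        fits = fit_gene_models(x, design)
        p1 = permutation_pvalues(fits, "fs", n_perm=150, seed=9)
        p2 = permutation_pvalues(fits, "fs", n_perm=150, seed=9)
        pd.testing.assert_series_equal(p1, p2)

    def test_pooled_mode_close_to_gene_specific_under_null(
        self, make_matrix, make_design
    ):
        rng = np.random.default_rng(6)
        x, design = _matrix_design(
            rng.standard_normal((100, 8)), make_matrix, make_design, 4
        )
        fits = fit_gene_models(x, design)
        p_pooled = permutation_pvalues(fits, "fs", n_perm=200, seed=1, pooled=True)
        assert ((p_pooled > 0) & (p_pooled <= 1)).all()
        # under homoscedastic null both modes target the same distribution
        p_gene = permutation_pvalues(fits, "fs", n_perm=200, seed=1)
        assert abs(p_pooled.mean() - p_gene.mean()) < 0.1

    def test_too_few_permutations_rejected(self, make_matrix, make_design):
        rng = np.random.default_rng(7)
        x, design = _matrix_design(
            rng.standard_normal((5, 8)), make_matrix, make_design, 4
        )
        fits = fit_gene_models(x, design)
        with pytest.raises(ValueError):
            permutation_pvalues(fits, "fs", n_perm=50)


class TestFdrAdjust:
    def test_hand_executed_step_up(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), np.ones(5))

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        order = np.argsort(p)
        m = p.size
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [
                m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(fdr_adjust(p), expected, rtol=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_to_input_order(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=50)
        assert (fdr_adjust(p) >= p - 1e-15).all()


class TestFoldChange:
    def test_equal_means_plus_one(self, make_matrix, make_design):
        x, design = _matrix_design([[1.0] * 8], make_matrix, make_design, 4)
        assert fold_change_lsmeans(fit_gene_models(x, design)).iloc[0] == 1.0

    def test_sign_convention_for_downregulation(self, make_matrix, make_design):
        x, design = _matrix_design(
            [[1.0, 1.0, 1.1, 0.9, 0.0, 0.0, 0.1, -0.1]], make_matrix, make_design, 4
        )
        assert fold_change_lsmeans(fit_gene_models(x, design)).iloc[0] == pytest.approx(
            -2.0
        )

    def test_matches_exponentiation_oracle(self, make_matrix, make_design):
        rng = np.random.default_rng(12)
        values = rng.standard_normal((25, 8))
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        fc = fold_change_lsmeans(fit_gene_models(x, design))
        for i in range(25):
            diff = values[i, 4:].mean() - values[i, :4].mean()
            raw = 2.0**diff
            expected = raw if raw >= 1 else -1.0 / raw
            assert fc.iloc[i] == pytest.approx(expected, rel=1e-12)
        assert (np.abs(fc) >= 1.0).all()


class TestF1Test:
    def test_equals_squared_pooled_t(self, make_matrix, make_design):
        rng = np.random.default_rng(13)
        values = rng.standard_normal((20, 10))
        x, design = _matrix_design(values, make_matrix, make_design, 5)
        table = f1_test(x, design)
        for i in range(20):
            t_res = stats.ttest_ind(values[i, :5], values[i, 5:], equal_var=True)
            assert table["statistic"].iloc[i] == pytest.approx(
                t_res.statistic**2, rel=1e-9
            )
            assert table["p_value"].iloc[i] == pytest.approx(t_res.pvalue, rel=1e-9)

    def test_identical_groups_boundary(self, make_matrix, make_design):
        x, design = _matrix_design([[2.0, 3.0, 4.0, 2.0, 3.0, 4.0]], make_matrix, make_design, 3)
        table = f1_test(x, design)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_null_pvalues_roughly_uniform(self, make_matrix, make_design):
        rng = np.random.default_rng(14)
        values = rng.standard_normal((2000, 8))
        x, design = _matrix_design(values, make_matrix, make_design, 4)
        p = f1_test(x, design)["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


def test_power_nondecreasing_in_effect_size(make_matrix, make_design):
    """Detection power grows with the log2 effect over {0.5, 1, 2}."""
    rng = np.random.default_rng(16)
    powers = []
    for delta in (0.5, 1.0, 2.0):
        values = 0.5 * rng.standard_normal((300, 16))
        values[:, 8:] += delta
        x, design = _matrix_design(values, make_matrix, make_design, 8)
        p = f1_test(x, design)["p_value"].to_numpy()
        powers.append((p < 0.05).mean())
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > 0.95


class TestDifferentialExpression:
    def test_full_table_contract(self, make_matrix, make_design):
        rng = np.random.default_rng(15)
        values = rng.standard_normal((40, 16))
        values[:5, 8:] += 4.0
        x, design = _matrix_design(values, make_matrix, make_design, 8)
        table = differential_expression(x, design, stat="fs", n_perm=200, seed=3)
        assert set(table.columns) >= {
            "statistic",
            "p_value",
            "q_value",
            "fold_change",
            "significant",
        }
        assert ((table["q_value"] >= table["p_value"] - 1e-12)).all()
        assert table["q_value"].between(0, 1).all()
        assert table.loc[table.index[:5], "significant"].all()
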