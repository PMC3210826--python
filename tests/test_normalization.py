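"""Normalization: LOWESS dye-bias removal, quantile normalization,
present calls, replicate collapsing and array QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxsetpipe.containers import ExpressionMatrix
from toxsetpipe.normalization import (
    collapse_replicates,
    lowess_normalize,
    ma_transform,
    present_call,
    qc_flag_outlier_arrays,
    quantile_normalize,
)
from toxsetpipe.synthetic import SimulationConfig, dye_bias_curve, generate_two_color


def _pair_from_ma(m: np.ndarray, a: np.ndarray, samples=None) -> tuple:
    red = 2.0 ** (a + m / 2.0)
    green = 2.0 ** (a - m / 2.0)
    probes = [f"g{i:04d}" for i in range(m.shape[0])]
    samples = samples or [f"s{j}" for j in range(m.shape[1])]
    return (
        ExpressionMatrix(pd.DataFrame(red, index=probes, columns=samples)),
        ExpressionMatrix(pd.DataFrame(green, index=probes, columns=samples)),
    )


class TestLowessNormalize:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, size=(400, 2))
        m = np.full((400, 2), 1.7)
        red, green = _pair_from_ma(m, a)
        out = lowess_normalize(red, green)
        assert np.nanmax(np.abs(out.values.to_numpy())) < 1e-6

    def test_linear_trend_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, size=(500, 2))
        m = 0.5 * a
        red, green = _pair_from_ma(m, a)
        out = lowess_normalize(red, green)
        interior = (a > np.quantile(a, 0.05)) & (a < np.quantile(a, 0.95))
        assert np.nanmax(np.abs(out.values.to_numpy()[interior])) < 0.02

    def test_synthetic_dye_bias_roundtrip(self):
        """The injected noiseless dye-bias curve is recovered to <1% of its
        amplitude on the interior intensity range."""
        config = SimulationConfig(n_genes=1000, variance_scale=0.0, seed=11)
        red, green, _, _ = generate_two_color(config)
        a = ma_transform(red, green).A.to_numpy()
        residual = lowess_normalize(red, green).values.to_numpy()
        bias = dye_bias_curve(config, a)
        amplitude = bias.max() - bias.min()
        interior = (a > np.quantile(a, 0.1)) & (a < np.quantile(a, 0.9))
        assert np.nanmax(np.abs(residual[interior])) < 0.01 * amplitude

    def test_nonpositive_channel_returned_as_missing(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, size=(50, 2))
        red, green = _pair_from_ma(np.zeros((50, 2)), a)
        red.values.iloc[0, 0] = 0.0
        out = lowess_normalize(red, green)
        assert np.isnan(out.values.iloc[0, 0])
        assert np.isfinite(out.values.iloc[1:, 0]).all()

    def test_bias_free_contrasts_preserved_in_expectation(self):
        """On bias-free data, normalization leaves the treatment contrast
        unchanged in expectation (paired comparison, 3*SE tolerance)."""
        config = SimulationConfig(
            n_genes=400, dye_bias=(0.0,), frac_de_genes=0.2, de_effect=1.0, seed=23
        )
        red, green, design, _ = generate_two_color(config)
        m_before = ma_transform(red, green).M
        m_after = lowess_normalize(red, green).values
        treated = design.samples_of("treated")
        control = design.samples_of("control")

        def contrast(m):
            return m[treated].mean(axis=1) - m[control].mean(axis=1)

        paired_shift = (contrast(m_after) - contrast(m_before)).to_numpy()
        se = paired_shift.std(ddof=1) / np.sqrt(paired_shift.size)
        assert abs(paired_shift.mean()) < 3 * se + 1e-4

    def test_invalid_span_rejected(self):
        red, green = _pair_from_ma(np.zeros((20, 2)), np.full((20, 2), 8.0))
        with pytest.raises(ValueError):
            lowess_normalize(red, green, span=0.0)


class TestQuantileNormalize:
    def test_hand_computed_example(self, make_matrix):
        x = make_matrix([[2, 8], [6, 2], [4, 4]], log_scale=False)
        out = quantile_normalize(x).values.to_numpy()
        np.testing.assert_allclose(out, [[2, 7], [7, 2], [4, 4]])

    def test_identical_columns_fixed_point(self, make_matrix):
        col = [3.0, 1.0, 5.0, 2.0]
        x = make_matrix(np.column_stack([col, col, col]), log_scale=False)
        np.testing.assert_allclose(
            quantile_normalize(x).values.to_numpy(), x.values.to_numpy()
        )

    @given(seed=st.integers(0, 1000))
    def test_idempotent_and_rank_preserving(self, make_matrix, seed):
        rng = np.random.default_rng(seed)
        x = make_matrix(rng.uniform(1, 100, size=(30, 4)), log_scale=False)
        once = quantile_normalize(x)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )
        for col in x.values:
            before = x.values[col].rank(method="average")
            after = once.values[col].rank(method="average")
            assert (before == after).all()

    def test_missing_values_rejected(self, make_matrix):
        x = make_matrix([[1.0, 2.0], [np.nan, 3.0]], log_scale=True)
        with pytest.raises(ValueError):
            quantile_normalize(x)


def _with_nc(values: np.ndarray, n_nc: int) -> ExpressionMatrix:
    probes = [f"p{i}" for i in range(values.shape[0])]
    ann = pd.DataFrame(
        {"negative_control": [i < n_nc for i in range(values.shape[0])]},
        index=probes,
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=[f"s{j}" for j in range(values.shape[1])]),
        annotations=ann,
    )


class TestPresentCall:
    def test_zero_spread_strict_boundary(self):
        # all NC at 10 -> threshold exactly 10; calls must use strict '>'
        vals = np.array([[10.0], [10.0], [10.0], [10.0], [10.5]])
        x = _with_nc(vals, 3)
        calls = present_call(x, trim=0.0)
        assert not calls.iloc[3, 0]  # at the threshold
        assert calls.iloc[4, 0]  # above it

    def test_threshold_matches_direct_arithmetic(self):
        nc = np.array([6.0, 8.0, 10.0, 12.0, 14.0])
        vals = np.concatenate([nc, [19.0, 20.0]])[:, None]
        x = _with_nc(vals, 5)
        calls = present_call(x, trim=0.0)
        threshold = nc.mean() + 3 * nc.std(ddof=1)
        assert not calls.iloc[5, 0] and (19.0 <= threshold)
        assert calls.iloc[6, 0] == (20.0 > threshold)

    def test_trimming_discards_extreme_outlier(self):
        nc_clean = np.linspace(8, 12, 19)
        nc_outlier = np.concatenate([nc_clean, [1000.0]])
        x = _with_nc(np.concatenate([nc_outlier, [15.0]])[:, None], 20)
        calls = present_call(x, trim=0.1)
        k = int(np.floor(0.1 * 20))
        core = np.sort(nc_outlier)[k:-k]
        threshold = core.mean() + 3 * core.std(ddof=1)
        assert calls.iloc[20, 0] == (15.0 > threshold)
        # untrimmed threshold would have swallowed the probe
        untrimmed = nc_outlier.mean() + 3 * nc_outlier.std(ddof=1)
        assert 15.0 <= untrimmed

    def test_too_few_controls_rejected(self):
        x = _with_nc(np.ones((4, 1)), 2)
        with pytest.raises(ValueError):
            present_call(x)


class TestCollapseReplicates:
    def _replicated(self, values, targets):
        probes = [f"p{i}" for i in range(len(targets))]
        ann = pd.DataFrame({"target": targets}, index=probes)
        return ExpressionMatrix(
            pd.DataFrame(values, index=probes, columns=["s1"]), annotations=ann
        )

    def test_single_probe_identity(self):
        x = self._replicated([[5.0], [7.0]], ["a", "b"])
        out = collapse_replicates(x)
        assert out.values.loc["a", "s1"] == 5.0
        assert out.values.loc["b", "s1"] == 7.0

    def test_median_robust_to_outlier(self):
        x = self._replicated([[1.0], [2.0], [100.0]], ["a", "a", "a"])
        assert collapse_replicates(x).values.loc["a", "s1"] == 2.0

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(5)
        targets = rng.choice(["a", "b", "c"], size=20).tolist()
        values = rng.uniform(1, 100, size=(20, 3))
        probes = [f"p{i}" for i in range(20)]
        ann = pd.DataFrame({"target": targets}, index=probes)
        x = ExpressionMatrix(
            pd.DataFrame(values, index=probes, columns=["s1", "s2", "s3"]),
            annotations=ann,
        )
        out = collapse_replicates(x)
        for tgt in "abc":
            rows = [i for i, t in enumerate(targets) if t == tgt]
            for j, s in enumerate(["s1", "s2", "s3"]):
                assert out.values.loc[tgt, s] == pytest.approx(
                    np.median(values[rows, j])
                )


class TestQcFlagOutlierArrays:
    def test_identical_arrays_unflagged(self, make_matrix):
        col = np.arange(10, dtype=float)
        x = make_matrix(np.column_stack([col, col, col]), log_scale=True)
        assert qc_flag_outlier_arrays(x, threshold=0.9) == []

    def test_noise_array_flagged(self, make_matrix):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 10, size=200)
        cols = [base + 0.1 * rng.standard_normal(200) for _ in range(4)]
        cols.append(rng.uniform(0, 10, size=200))  # unrelated array
        x = make_matrix(np.column_stack(cols), log_scale=True)
        assert qc_flag_outlier_arrays(x, threshold=0.5) == [x.samples[-1]]

    def test_vacuous_threshold_never_flags(self, make_matrix):
        rng = np.random.default_rng(9)
        x = make_matrix(rng.uniform(0, 1, size=(50, 4)), log_scale=True)
        assert qc_flag_outlier_arrays(x, threshold=-1.0) == []
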