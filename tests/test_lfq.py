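"""Valid-value filtering, downshifted imputation and the two-group t-test."""

import numpy as np
import pandas as pd
import pytest

from hlatarget.io import LfqMatrix
from hlatarget.lfq import (
    ImputationParams,
    differential_test,
    impute,
    preprocess,
    volcano_table,
)
from hlatarget.synthetic import simulate_lfq_experiment

GROUPS = {f"A_{i}": "A" for i in range(1, 4)} | {f"B_{i}": "B" for i in range(1, 4)}


def _matrix(rows, log_scale=False):
    df = pd.DataFrame(rows, columns=list(GROUPS)).astype(float)
    df.index = [f"P{i}" for i in range(len(df))]
    return LfqMatrix(df, GROUPS, log_scale=log_scale)


class TestPreprocess:
    def test_valid_value_rule(self):
        m = _matrix(
            [
                [100, 110, 120, np.nan, np.nan, np.nan],  # 3/3 in A -> kept
                [100, 110, np.nan, 90, 95, np.nan],       # 2/3 and 2/3 -> dropped
                [100, 110, 120, 90, 95, 85],              # complete -> kept
            ]
        )
        out = preprocess(m)
        assert out.proteins == ["P0", "P2"]
        assert out.log_scale
        assert out.data.loc["P2", "A_1"] == pytest.approx(np.log2(100))

    def test_complete_matrix_only_log_transformed(self):
        m = _matrix([[100, 110, 120, 90, 95, 85]])
        out = preprocess(m)
        assert out.proteins == ["P0"]
        assert np.allclose(out.data.to_numpy(), np.log2(m.data.to_numpy()))

    def test_idempotent(self):
        m = _matrix([[100, 110, 120, 90, 95, 85], [100, np.nan, np.nan, np.nan, np.nan, 85]])
        once = preprocess(m)
        twice = preprocess(once)
        assert once == twice

    def test_small_group_warns_and_uses_other_groups(self):
        groups = {"A_1": "A", "B_1": "B", "B_2": "B", "B_3": "B"}
        df = pd.DataFrame([[100.0, 90.0, 95.0, 85.0]], columns=list(groups), index=["P0"])
        with pytest.warns(UserWarning, match="'A'"):
            out = preprocess(LfqMatrix(df, groups))
        assert out.proteins == ["P0"]


class TestImpute:
    def test_observed_cells_never_altered(self):
        m = preprocess(_matrix([[100, 110, 120, 90, 95, np.nan],
                                [100, 110, 120, 90, 95, 85],
                                [105, 115, 125, 95, 100, 90]]))
        out = impute(m, ImputationParams(seed=1))
        observed = ~m.data.isna()
        assert np.allclose(out.data.to_numpy()[observed], m.data.to_numpy()[observed])
        assert not out.data.isna().any().any()

    def test_downshifted_distribution_parameters(self):
        # one sample with mean 25, sd 1 and many missing entries: imputed
        # mean must sit at 25 - 1.8 = 23.2 within monte-carlo error
        rng = np.random.default_rng(0)
        n = 4000
        col = rng.normal(25, 1, n)
        data = pd.DataFrame(
            {
                "A_1": np.concatenate([col, [np.nan] * 1000]),
                "A_2": rng.normal(25, 1, n + 1000),
                "A_3": rng.normal(25, 1, n + 1000),
                "B_1": rng.normal(25, 1, n + 1000),
                "B_2": rng.normal(25, 1, n + 1000),
                "B_3": rng.normal(25, 1, n + 1000),
            }
        )
        data.index = [f"P{i}" for i in range(len(data))]
        m = LfqMatrix(data, GROUPS, log_scale=True)
        out = impute(m, ImputationParams(width=0.3, downshift=1.8, seed=2))
        imputed = out.data["A_1"].tail(1000)
        assert imputed.mean() == pytest.approx(
            col.mean() - 1.8 * col.std(ddof=1), abs=0.1
        )
        assert imputed.std(ddof=1) == pytest.approx(0.3 * col.std(ddof=1), rel=0.15)

    def test_width_zero_is_degenerate_at_downshifted_mean(self):
        m = preprocess(_matrix([[100, np.nan, 120, 90, 95, 85],
                                [100, 105, 120, 90, 95, 85],
                                [110, 118, 130, 92, 97, 88]]))
        out = impute(m, ImputationParams(width=0.0, seed=3))
        col = m.data["A_2"].dropna()
        expected = col.mean() - 1.8 * col.std(ddof=1)
        assert out.data.loc["P0", "A_2"] == pytest.approx(expected)

    def test_same_seed_identical(self):
        m = preprocess(_matrix([[100, np.nan, 120, 90, np.nan, 85],
                                [100, 105, 120, 90, 95, 85],
                                [110, 118, 130, 92, 97, 88]]))
        a = impute(m, ImputationParams(seed=7))
        b = impute(m, ImputationParams(seed=7))
        assert a == b

    def test_sample_with_too_few_observations_is_error(self):
        df = pd.DataFrame(
            {"A_1": [1.0, np.nan], "A_2": [1.0, 2.0], "A_3": [1.0, 2.0],
             "B_1": [1.0, 2.0], "B_2": [1.0, 2.0], "B_3": [1.0, 2.0]},
            index=["P0", "P1"],
        )
        m = LfqMatrix(df, GROUPS, log_scale=True)
        with pytest.raises(ValueError, match="A_1"):
            impute(m, ImputationParams())


class TestDifferentialTest:
    def test_identical_groups_give_zero_fc_p_one(self):
        m = _matrix([[10, 11, 12, 10, 11, 12]], log_scale=True)
        res = differential_test(m)
        assert res.log2_fc.iloc[0] == 0.0
        assert res.p_value.iloc[0] == pytest.approx(1.0)
        assert res.status.iloc[0] == "ns"

    def test_pooled_t_statistic_worked_example(self):
        # scipy oracle for (5.0, 5.1, 4.9) vs (3.0, 3.1, 2.9):
        # t = 24.4949, p = 1.648e-5
        m = _matrix([[5.0, 5.1, 4.9, 3.0, 3.1, 2.9]], log_scale=True)
        res = differential_test(m)
        assert res.t_stat.iloc[0] == pytest.approx(24.4949, abs=1e-3)
        assert res.p_value.iloc[0] == pytest.approx(1.648e-5, rel=1e-3)
        assert res.log2_fc.iloc[0] == pytest.approx(2.0)
        assert res.status.iloc[0] == "up"

    def test_zero_variance_equal_means_p_one(self):
        m = _matrix([[5, 5, 5, 5, 5, 5]], log_scale=True)
        res = differential_test(m)
        assert res.p_value.iloc[0] == 1.0

    def test_null_experiment_bh_calls_near_zero(self):
        fracs = []
        for seed in range(5):
            matrix, _ = simulate_lfq_experiment(
                n_proteins=400, frac_de=0.0, dropout_midpoint=-1e9, seed=seed
            )
            res = differential_test(preprocess(matrix))
            fracs.append((res.p_adjusted <= 0.05).mean())
        assert np.mean(fracs) < 0.01

    def test_pvalues_uniform_under_global_null(self):
        from scipy import stats

        matrix, _ = simulate_lfq_experiment(
            n_proteins=2000, frac_de=0.0, dropout_midpoint=-1e9, seed=42
        )
        res = differential_test(preprocess(matrix))
        assert stats.kstest(res.p_value, "uniform").pvalue > 0.01

    def test_requires_two_groups(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"], index=["P0"])
        m = LfqMatrix(df, {"a": "A", "b": "A"}, log_scale=True)
        with pytest.raises(ValueError, match="two groups"):
            differential_test(m)


def test_volcano_table_log_identity():
    m = _matrix([[5.0, 5.1, 4.9, 3.0, 3.1, 2.9]], log_scale=True)
    res = differential_test(m)
    v = volcano_table(res)
    assert v.neg_log10_p.iloc[0] == pytest.approx(-np.log10(res.p_value.iloc[0]))
    assert list(v.columns) == ["log2_fc", "neg_log10_p", "neg_log10_p_adjusted", "status"]
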