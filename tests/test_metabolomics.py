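import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nadscope.metabolomics import (
    cyclic_loess_normalize,
    filter_missingness,
    log2_assemble,
    qrilc_impute,
)


class TestLog2Assemble:
    def test_values_and_mask(self, matrix_builder):
        vals = np.array([[8.0, np.nan], [2.0, 4.0]])
        m = matrix_builder(vals, ["Young", "OldControl"], log_scale=False)
        out = log2_assemble(m)
        assert out.values.iloc[0, 0] == 3.0
        assert np.isnan(out.values.iloc[0, 1])
        assert out.log_scale

    def test_roundtrip(self, matrix_builder):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, (10, 4))
        m = matrix_builder(vals, ["Young"] * 2 + ["OldControl"] * 2, log_scale=False)
        out = log2_assemble(m)
        assert np.allclose(2.0 ** out.values.to_numpy(), vals, rtol=1e-12)

    def test_nonpositive_cells_named_in_error(self, matrix_builder):
        vals = np.array([[1.0, -2.0], [3.0, 4.0]])
        m = matrix_builder(vals, ["Young", "OldControl"], log_scale=False)
        with pytest.raises(ValueError, match=r"\(m0, s1\)"):
            log2_assemble(m)


class TestCyclicLoess:
    def test_identical_samples_are_fixed_point(self, matrix_builder):
        base = np.random.default_rng(1).normal(20, 2, 50)
        m = matrix_builder(np.column_stack([base, base]), ["Young", "OldControl"])
        out = cyclic_loess_normalize(m)
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_constant_offset_removed(self, matrix_builder):
        base = np.random.default_rng(2).normal(20, 2, 200)
        c = 1.0
        m = matrix_builder(np.column_stack([base + c, base]), ["Young", "OldControl"])
        out = cyclic_loess_normalize(m)
        med = np.median(out.values.iloc[:, 0] - out.values.iloc[:, 1])
        assert abs(med) < 0.01 * c

    def test_intensity_dependent_bias_removed(self, matrix_builder):
        rng = np.random.default_rng(3)
        base = rng.normal(20, 2, 300)
        xj = base + rng.normal(0, 0.05, 300)
        xi = base + 0.3 * (base - base.mean()) + rng.normal(0, 0.05, 300)
        m = matrix_builder(np.column_stack([xi, xj]), ["Young", "OldControl"])
        out = cyclic_loess_normalize(m)
        mm = out.values.iloc[:, 0] - out.values.iloc[:, 1]
        aa = (out.values.iloc[:, 0] + out.values.iloc[:, 1]) / 2
        slope = np.polyfit(aa, mm, 1)[0]
        assert abs(slope) < 0.02

    def test_pair_grand_mean_preserved(self, matrix_builder):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 2, (100, 3))
        vals[:, 0] += 0.2 * (vals[:, 0] - 20)
        m = matrix_builder(vals, ["Young", "OldControl", "OldNMN"])
        out = cyclic_loess_normalize(m)
        assert np.isclose(
            out.values.to_numpy().sum(), vals.sum(), rtol=0, atol=1e-8 * abs(vals.sum())
        )

    def test_missing_cells_untouched(self, matrix_builder):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 2, (60, 3))
        vals[:, 0] += 0.5
        vals[5, 1] = np.nan
        m = matrix_builder(vals, ["Young", "OldControl", "OldNMN"])
        out = cyclic_loess_normalize(m)
        assert np.isnan(out.values.iloc[5, 1])
        assert out.mask.to_numpy().sum() == 1

    def test_insufficient_shared_cells_rejected(self, matrix_builder):
        vals = np.full((5, 2), 20.0)
        m = matrix_builder(vals, ["Young", "OldControl"])
        with pytest.raises(ValueError, match="fewer than"):
            cyclic_loess_normalize(m)


class TestFilterMissingness:
    def test_half_missing_excluded_exact_threshold_retained(self, matrix_builder):
        vals = np.ones((3, 10)) * 20
        vals[0, :5] = np.nan  # 50% -> excluded
        vals[1, :4] = np.nan  # exactly 40% -> retained
        m = matrix_builder(vals, ["Young"] * 5 + ["OldControl"] * 5)
        out = filter_missingness(m, threshold=0.40)
        assert list(out.values.index) == ["m1", "m2"]

    def test_complete_matrix_unchanged(self, matrix_builder):
        vals = np.random.default_rng(0).normal(20, 1, (4, 6))
        m = matrix_builder(vals, ["Young"] * 3 + ["OldControl"] * 3)
        out = filter_missingness(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent(self, matrix_builder):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, (20, 10))
        vals[rng.uniform(size=vals.shape) < 0.3] = np.nan
        m = matrix_builder(vals, ["Young"] * 5 + ["OldControl"] * 5)
        once = filter_missingness(m)
        twice = filter_missingness(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestQrilc:
    def test_complete_matrix_passes_through(self, matrix_builder):
        vals = np.random.default_rng(0).normal(20, 1, (30, 4))
        m = matrix_builder(vals, ["Young"] * 2 + ["OldControl"] * 2)
        out, params = qrilc_impute(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert (params.missing_fraction == 0).all()

    def test_truncated_normal_parameter_recovery(self, matrix_builder):
        rng = np.random.default_rng(7)
        x = rng.normal(20, 1.5, 2000)
        cut = np.quantile(x, 0.05)
        censored = np.where(x < cut, np.nan, x)
        vals = np.column_stack([censored, rng.normal(20, 1.5, 2000)])
        m = matrix_builder(vals, ["Young", "OldControl"])
        out, params = qrilc_impute(m, seed=2)
        assert abs(params.mu_hat.iloc[0] - 20.0) < 0.1
        assert abs(params.sigma_hat.iloc[0] - 1.5) < 0.1
        # every imputed value lies below the truncation point
        imputed = out.values.to_numpy()[np.isnan(vals)]
        assert (imputed < params.truncation_point.iloc[0]).all()

    def test_observed_cells_never_altered(self, matrix_builder):
        rng = np.random.default_rng(8)
        vals = rng.normal(20, 1, (200, 3))
        vals[vals < 19.0] = np.nan
        m = matrix_builder(vals, ["Young", "OldControl", "OldNMN"])
        out, _ = qrilc_impute(m, seed=3)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_seed_contract(self, matrix_builder):
        rng = np.random.default_rng(9)
        vals = rng.normal(20, 1, (100, 2))
        vals[vals < 19.2] = np.nan
        m = matrix_builder(vals, ["Young", "OldControl"])
        a, _ = qrilc_impute(m, seed=5)
        b, _ = qrilc_impute(m, seed=5)
        c, _ = qrilc_impute(m, seed=6)
        pd.testing.assert_frame_equal(a.values, b.values)
        miss = np.isnan(vals)
        assert not np.array_equal(a.values.to_numpy()[miss], c.values.to_numpy()[miss])
        assert np.array_equal(a.values.to_numpy()[~miss], c.values.to_numpy()[~miss])

    def test_too_few_observed_values_rejected(self, matrix_builder):
        vals = np.full((6, 2), np.nan)
        vals[:2, 0] = 20.0
        vals[:, 1] = 20.0 + np.arange(6)
        m = matrix_builder(vals, ["Young", "OldControl"])
        with pytest.raises(ValueError):
            qrilc_impute(m, seed=0)
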