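import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import nadscope.moderated as mod
from nadscope.moderated import (
    ModeratedLinearModel,
    bh_fdr,
    estimate_variance_prior,
    fold_changes,
    trigamma_inverse,
)


def bh_oracle(p):
    """Step-up definition: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def null_matrix(seed, n_met=60, n_per=8, matrix_builder=None):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    vals = rng.normal(20, 0.5, (n_met, n))
    groups = ["Young"] * n_per + ["OldControl"] * n_per
    batches = [f"b{k % 2}" for k in range(n)]
    protein = rng.normal(0, 1, n)
    return matrix_builder(vals, groups, batches, protein)


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.1, 0.5, 2.0, 25.0])
    def test_roundtrip(self, x):
        y = float(special.polygamma(1, x))
        assert np.isclose(trigamma_inverse(y), x, rtol=1e-8)

    def test_nonpositive_input_gives_inf(self):
        assert trigamma_inverse(0.0) == np.inf
        assert trigamma_inverse(-1.0) == np.inf


class TestVariancePrior:
    def test_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, d = 4.0, 0.25, 10
        sigma2 = s0_sq * d0 / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        d0_hat, s0_hat = estimate_variance_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_sq) / s0_sq < 0.1

    def test_equal_variances_disable_moderation(self, matrix_builder):
        # duplicated response rows -> identical s2_g -> no spread to shrink
        rng = np.random.default_rng(1)
        row = rng.normal(20, 0.5, 12)
        vals = np.tile(row, (5, 1))
        m = matrix_builder(vals, ["Young"] * 6 + ["OldControl"] * 6)
        with pytest.warns(RuntimeWarning, match="unmoderated"):
            res = ModeratedLinearModel(
                m, batch_covariate=False, protein_covariate=False
            ).fit()
        assert not np.isfinite(res.d0)
        assert np.allclose(res.table.s2_tilde, res.table.s2_g, rtol=1e-12)


class TestModeratedModel:
    def test_zero_prior_df_limit_equals_ordinary_t(self, matrix_builder, monkeypatch):
        m = null_matrix(3, matrix_builder=matrix_builder)
        monkeypatch.setattr(
            mod, "estimate_variance_prior", lambda s2, df: (0.0, 1.0)
        )
        res = ModeratedLinearModel(m).fit()
        t_ols = res.table.beta_log2 / res.table.se_beta_ols
        assert np.allclose(res.table.t_moderated, t_ols, atol=1e-10)

    def test_moderated_variance_between_prior_and_sample(self, matrix_builder):
        m = null_matrix(4, matrix_builder=matrix_builder)
        res = ModeratedLinearModel(m).fit()
        lo = np.minimum(res.table.s2_g, res.s0_sq)
        hi = np.maximum(res.table.s2_g, res.s0_sq)
        assert ((res.table.s2_tilde >= lo - 1e-12) & (res.table.s2_tilde <= hi + 1e-12)).all()

    def test_null_type_one_error_near_nominal(self, matrix_builder):
        fracs = []
        for seed in range(30):
            m = null_matrix(seed, n_met=100, matrix_builder=matrix_builder)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ModeratedLinearModel(m).fit()
            fracs.append((res.table.p < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.015

    def test_known_effect_recovered(self, matrix_builder):
        rng = np.random.default_rng(10)
        n_per, n_met = 10, 100
        vals = rng.normal(20, 0.5, (n_met, 2 * n_per))
        vals[:20, :n_per] += 1.0  # Young effect of +1 log2 on first 20
        m = matrix_builder(vals, ["Young"] * n_per + ["OldControl"] * n_per)
        res = ModeratedLinearModel(m).fit()
        young = res.contrast("Young")
        assert abs(young.beta_log2.iloc[:20].mean() - 1.0) < 0.12
        assert abs(young.beta_log2.iloc[20:].mean()) < 0.12

    def test_rank_deficient_design_names_aliased_columns(self, matrix_builder):
        # batch perfectly confounded with group
        vals = np.random.default_rng(2).normal(20, 0.5, (10, 8))
        groups = ["Young"] * 4 + ["OldControl"] * 4
        batches = ["b1"] * 4 + ["b2"] * 4
        m = matrix_builder(vals, groups, batches)
        with pytest.raises(ValueError, match="aliased"):
            ModeratedLinearModel(m)

    def test_incomplete_matrix_rejected(self, matrix_builder):
        vals = np.random.default_rng(3).normal(20, 0.5, (5, 6))
        vals[0, 0] = np.nan
        m = matrix_builder(vals, ["Young"] * 3 + ["OldControl"] * 3)
        with pytest.raises(ValueError, match="complete"):
            ModeratedLinearModel(m)


class TestBhFdr:
    def test_worked_five_value_example(self):
        q, flags = bh_fdr([0.001, 0.01, 0.02, 0.5, 0.9])
        assert np.allclose(q, [0.005, 0.025, 1 / 30, 0.625, 0.9], atol=1e-10)
        assert list(flags) == [True, True, True, False, False]

    def test_all_ones(self):
        q, flags = bh_fdr([1.0] * 4)
        assert (q == 1.0).all() and not flags.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_oracle(self, pvals):
        q, _ = bh_fdr(pvals)
        assert np.allclose(q, bh_oracle(pvals), atol=1e-12)

    def test_duplicating_smallest_p_never_hurts(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(size=6)
            _, flags = bh_fdr(p)
            p2 = np.concatenate([p, [p.min()]])
            _, flags2 = bh_fdr(p2)
            assert (flags2[:6] | ~flags).all()  # flags never downgraded


class TestFoldChanges:
    def test_delta_method_against_monte_carlo(self):
        # se of 2^X for X ~ N(1, 0.1) via the delta method
        rng = np.random.default_rng(0)
        draws = 2.0 ** rng.normal(1.0, 0.1, 100_000)
        se_mc = draws.std(ddof=1)
        se_delta = np.log(2) * 2.0**1.0 * 0.1
        assert abs(se_delta - 0.1386) < 5e-4
        assert abs(se_mc - se_delta) / se_delta < 0.02

    def test_table_values_and_ordering(self, matrix_builder):
        rng = np.random.default_rng(21)
        vals = rng.normal(20, 0.4, (20, 16))
        vals[0, :8] += 1.0
        vals[1, :8] -= 1.0
        m = matrix_builder(vals, ["Young"] * 8 + ["OldControl"] * 8)
        res = ModeratedLinearModel(m).fit()
        fc = fold_changes(res, "Young")
        assert (fc.fc.diff().dropna() <= 1e-12).all()  # descending
        assert np.allclose(fc.fc, 2.0**fc.beta_log2)
        assert np.allclose(fc.se_fc, np.log(2) * fc.fc * fc.se_beta)
        up = fc.set_index("metabolite").loc["m0"]
        dn = fc.set_index("metabolite").loc["m1"]
        assert up.fc > 1.5 and dn.fc < 0.67
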