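import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nutrinet import (
    DesignInfo,
    ModerationParams,
    bh_adjust,
    call_degs,
    deg_table,
    estimate_moderation,
    fit_contrasts,
    moderated_statistics,
)


def brute_force_bh(p):
    """Independent step-up oracle: min over j>=i of p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


def two_group_matrix(t_vals, c_vals):
    data = {f"t{i}": [v] for i, v in enumerate(t_vals)}
    data.update({f"c{i}": [v] for i, v in enumerate(c_vals)})
    m = pd.DataFrame(data, index=["g"])
    groups = {f"t{i}": "T" for i in range(len(t_vals))}
    groups.update({f"c{i}": "C" for i in range(len(c_vals))})
    return m, DesignInfo(groups, ("T", "C"))


class TestFitContrasts:
    def test_noiseless_groups(self):
        m, d = two_group_matrix([4.0, 4.0], [2.0, 2.0])
        fit = fit_contrasts(m, d)
        assert fit["log2fc"].iloc[0] == pytest.approx(2.0)
        assert fit["residual_var"].iloc[0] == pytest.approx(0.0)

    def test_pooled_variance_by_hand(self):
        # s^2 = ((3-4)^2+(5-4)^2+(1-2)^2+(3-2)^2)/2 = 2 on df = 2
        m, d = two_group_matrix([3.0, 5.0], [1.0, 3.0])
        fit = fit_contrasts(m, d)
        assert fit["log2fc"].iloc[0] == pytest.approx(2.0)
        assert fit["residual_var"].iloc[0] == pytest.approx(2.0)
        assert fit["residual_df"].iloc[0] == pytest.approx(2.0)

    def test_sample_order_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        d = DesignInfo({c: ("T" if c in "abc" else "C") for c in "abcdef"}, ("T", "C"))
        shuffled = m[list("fcadbe")]
        pd.testing.assert_frame_equal(fit_contrasts(m, d), fit_contrasts(shuffled, d))

    def test_small_group_error(self):
        m, _ = two_group_matrix([1.0], [2.0, 3.0])
        d = DesignInfo({"t0": "T", "c0": "C", "c1": "C"}, ("T", "C"))
        with pytest.raises(ValueError, match=">=2 samples"):
            fit_contrasts(m, d)


class TestEstimateModeration:
    def test_identical_variances_take_infinite_prior(self):
        params = estimate_moderation(np.full(100, 0.3), residual_df=4)
        assert np.isinf(params.prior_df)
        assert params.prior_var == pytest.approx(0.3 * np.exp(0), rel=0.5)

    def test_scale_equivariance(self, rng):
        d0, s0, d = 4.0, 0.05, 4.0
        true_var = s0 * d0 / rng.chisquare(d0, 3000)
        s2 = true_var * rng.chisquare(d, 3000) / d
        a = estimate_moderation(s2, d)
        b = estimate_moderation(2 * s2, d)
        assert b.prior_var == pytest.approx(2 * a.prior_var, rel=1e-6)
        assert b.prior_df == pytest.approx(a.prior_df, rel=1e-6)

    def test_zero_variances_error(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_moderation(np.zeros(100), residual_df=4)

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError, match=">=30"):
            estimate_moderation(np.full(10, 0.5), residual_df=4)


class TestModeratedStatistics:
    def test_zero_effect_gives_unit_p(self):
        t, p = moderated_statistics(
            np.zeros(3), np.ones(3), 4, ModerationParams(4, 0.05), 3, 3
        )
        np.testing.assert_allclose(t, 0.0)
        np.testing.assert_allclose(p, 1.0)

    def test_prior_df_zero_is_ordinary_pooled_t(self, rng):
        xt = rng.normal(1, 1, (50, 4))
        xc = rng.normal(0, 1, (50, 4))
        m = pd.DataFrame(np.hstack([xt, xc]), columns=[f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)])
        d = DesignInfo({c: c[0].upper() for c in m.columns}, ("T", "C"))
        fit = fit_contrasts(m, d)
        # prior_df -> 0 limit through a tiny positive value
        t_mod, p_mod = moderated_statistics(
            fit["log2fc"].to_numpy(), fit["residual_var"].to_numpy(), 6.0,
            ModerationParams(1e-12, 1.0), 4, 4,
        )
        t_ref, p_ref = stats.ttest_ind(xt, xc, axis=1, equal_var=True)
        np.testing.assert_allclose(t_mod, t_ref, rtol=1e-5)
        np.testing.assert_allclose(p_mod, p_ref, rtol=1e-4)

    def test_prior_df_infinite_matches_normal_tail(self):
        lfc = np.array([0.5, -1.0, 2.0])
        t, p = moderated_statistics(
            lfc, np.array([0.1, 0.2, 0.3]), 4, ModerationParams(np.inf, 0.04), 3, 3
        )
        se = np.sqrt(0.04 * (2 / 3))
        np.testing.assert_allclose(t, lfc / se)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(lfc / se)))

    def test_posterior_variance_between_prior_and_residual(self, rng):
        s2 = rng.uniform(0.01, 1.0, 200)
        params = ModerationParams(4.0, 0.25)
        post = (params.prior_df * params.prior_var + 4 * s2) / (params.prior_df + 4)
        lo = np.minimum(s2, params.prior_var)
        hi = np.maximum(s2, params.prior_var)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_monotone_in_effect_at_fixed_variance(self):
        lfc = np.array([0.1, 0.5, 1.0, 2.0])
        t, _ = moderated_statistics(lfc, np.full(4, 0.2), 4, ModerationParams(4, 0.1), 3, 3)
        assert np.all(np.diff(t) > 0)


class TestBHAdjust:
    def test_stepup_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDegs:
    def test_both_gates_and_strict_fold_inequality(self):
        table = pd.DataFrame(
            {
                "log2fc": [2.0, 0.5, -1.5, 3.0, 1.0],
                "fdr": [0.01, 0.01, 0.2, 0.04, 0.01],
            },
            index=[f"gene{i}" for i in range(1, 6)],
        )
        # gene5 has |lfc| == 1.0 exactly and fails the strict > gate
        assert call_degs(table) == {"gene1", "gene4"}

    def test_empty_table(self):
        table = pd.DataFrame({"log2fc": [], "fdr": []})
        assert call_degs(table) == set()


def test_deg_table_null_calibration(rng):
    """Zero-effect data: p roughly uniform, BH discoveries rare."""
    n = 4000
    m = pd.DataFrame(
        rng.normal(8, 0.5, (n, 6)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{i}" for i in range(6)],
    )
    d = DesignInfo({f"s{i}": ("T" if i < 3 else "C") for i in range(6)}, ("T", "C"))
    table = deg_table(m, d)
    frac = (table["p_value"] < 0.05).mean()
    assert 0.03 < frac < 0.07
    assert table["is_deg"].sum() <= 2
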