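import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as st

import metaroast as mr
from metaroast.diffstats import DesignError, GroupDesign, posterior_s2
from metaroast.preprocess import NormalizedMatrix


def _nm(wt: np.ndarray, ko: np.ndarray) -> tuple[NormalizedMatrix, list]:
    """Wrap per-feature WT/KO arrays (m x n1, m x n2) as a matrix + metadata."""
    wt, ko = np.atleast_2d(wt), np.atleast_2d(ko)
    n1, n2 = wt.shape[1], ko.shape[1]
    cols = [f"wt{i}" for i in range(n1)] + [f"ko{i}" for i in range(n2)]
    df = pd.DataFrame(np.hstack([wt, ko]), columns=cols)
    df.index = [f"f{i}" for i in range(len(df))]
    plat = pd.Series("gcms", index=df.index)
    samples = [
        mr.SampleInfo(c, "WT" if c.startswith("wt") else "KO") for c in cols
    ]
    mask = pd.DataFrame(False, index=df.index, columns=cols)
    return NormalizedMatrix(df, plat, pd.DataFrame(), mask), samples


def test_fit_two_group_hand_example():
    nm, samples = _nm([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    fit, design = mr.fit_two_group(nm, samples)
    row = fit.iloc[0]
    assert row["logFC"] == pytest.approx(3.0)
    assert row["aveExpr"] == pytest.approx(3.5)
    assert row["s2"] == pytest.approx(1.0)
    assert design.df_residual == 4


def test_fit_identical_groups_gives_zero_logfc():
    nm, samples = _nm([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    fit, _ = mr.fit_two_group(nm, samples)
    assert fit["logFC"].iloc[0] == 0.0


def test_fit_invariant_to_sample_order():
    rng = np.random.default_rng(1)
    nm, samples = _nm(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))
    fit1, _ = mr.fit_two_group(nm, samples)
    perm = [samples[i] for i in rng.permutation(len(samples))]
    cols = [s.sample_id for s in perm]
    nm2 = NormalizedMatrix(nm.values[cols], nm.platform, pd.DataFrame(), nm.imputed[cols])
    fit2, _ = mr.fit_two_group(nm2, perm)
    pd.testing.assert_frame_equal(fit1, fit2)


def test_fit_requires_both_groups():
    nm, samples = _nm(np.ones((2, 3)), np.ones((2, 3)))
    only_wt = [mr.SampleInfo(s.sample_id, "WT") for s in samples]
    with pytest.raises(DesignError):
        mr.fit_two_group(nm, only_wt)


# --- prior estimation -------------------------------------------------------


def test_equal_variances_give_infinite_d0():
    prior = mr.estimate_prior(np.full(50, 0.7), 4)
    assert math.isinf(prior.d0)
    assert prior.s0_2 == pytest.approx(0.7)


def test_prior_recovery_from_hierarchical_simulation():
    # oracle: simulate the full variance hierarchy and recover (d0, s0_2)
    rng = np.random.default_rng(123)
    d0, s0_2, d, m = 4.0, 1.0, 10, 5000
    sigma2 = s0_2 * d0 / rng.chisquare(d0, size=m)
    s2 = sigma2 * rng.chisquare(d, size=m) / d
    prior = mr.estimate_prior(s2, d)
    assert prior.d0 == pytest.approx(d0, rel=0.10)
    assert prior.s0_2 == pytest.approx(s0_2, rel=0.10)


def test_prior_needs_ten_features():
    with pytest.raises(DesignError, match=">= 10"):
        mr.estimate_prior(np.ones(5), 4)


def test_prior_rejects_all_zero_variances():
    with pytest.raises(DesignError, match="zero"):
        mr.estimate_prior(np.zeros(20), 4)


# --- moderated t ------------------------------------------------------------


def test_moderated_t_reduces_to_pooled_t_without_prior():
    t, df, p = mr.moderated_t(np.array([3.0]), np.array([1.0]), GroupDesign(3, 3), None)
    assert t[0] == pytest.approx(3.674, abs=1e-3)
    assert df == 4
    assert p[0] == pytest.approx(0.0213, abs=1e-3)


def test_moderated_t_with_prior_gains_df():
    prior = mr.EBayesPrior(d0=4.0, s0_2=1.0)
    t, df, p = mr.moderated_t(np.array([3.0]), np.array([1.0]), GroupDesign(3, 3), prior)
    # posterior variance (4*1 + 4*1)/8 = 1: t unchanged, df doubled
    assert t[0] == pytest.approx(3.674, abs=1e-3)
    assert df == 8
    assert p[0] == pytest.approx(0.00627, abs=2e-4)


def test_zero_logfc_gives_p_one():
    t, _, p = mr.moderated_t(np.array([0.0]), np.array([1.0]), GroupDesign(3, 3), None)
    assert t[0] == 0.0
    assert p[0] == 1.0


def test_no_shrinkage_limit_matches_textbook_t():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n1, n2 = rng.integers(2, 8, size=2)
        wt = rng.normal(size=n1)
        ko = rng.normal(size=n2)
        nm, samples = _nm(wt, ko)
        fit, design = mr.fit_two_group(nm, samples)
        t, df, p = mr.moderated_t(
            fit["logFC"].to_numpy(), fit["s2"].to_numpy(), design, None
        )
        t_ref, p_ref = st.ttest_ind(ko, wt, equal_var=True)
        assert t[0] == pytest.approx(t_ref)
        assert p[0] == pytest.approx(p_ref)


def test_infinite_shrinkage_limit_is_normal_test():
    rng = np.random.default_rng(8)
    lfc = rng.normal(size=30)
    s2 = rng.chisquare(4, size=30)
    prior = mr.EBayesPrior(d0=math.inf, s0_2=0.5)
    design = GroupDesign(6, 6)
    t, df, p = mr.moderated_t(lfc, s2, design, prior)
    se = math.sqrt(0.5) * design.stdev_unscaled
    np.testing.assert_allclose(t, lfc / se)
    assert math.isinf(df)
    np.testing.assert_allclose(p, 2 * st.norm.sf(np.abs(lfc / se)))


def test_posterior_variance_interpolates():
    prior = mr.EBayesPrior(d0=4.0, s0_2=2.0)
    out = posterior_s2(np.array([1.0]), 4.0, prior)
    assert out[0] == pytest.approx(1.5)


# --- BH ---------------------------------------------------------------------


def _bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Adjusted p by exhaustive cutoff search: adj_i = min alpha at which
    the step-up procedure rejects hypothesis i."""
    m = len(p)
    out = np.ones(m)
    order = np.argsort(p, kind="stable")
    for i, idx in enumerate(order):
        # smallest alpha with p_(j) <= alpha*j/m for some j >= rank(i)
        out[idx] = min(p[order[j]] * m / (j + 1) for j in range(i, m))
    return np.minimum(out, 1.0)


def test_bh_hand_example():
    np.testing.assert_allclose(
        mr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_unchanged():
    assert mr.bh_adjust([0.3])[0] == 0.3


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        mr.bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st_.lists(
        st_.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8
    )
)
def test_bh_matches_brute_force_cutoff_search(p):
    p = np.asarray(p)
    np.testing.assert_allclose(mr.bh_adjust(p), _bh_brute_force(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    p = rng.uniform(size=500)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(mr.bh_adjust(p), ref, atol=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st_.lists(
        st_.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20
    )
)
def test_bh_adjusted_at_least_raw_and_rank_monotone(p):
    p = np.asarray(p)
    adj = mr.bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


# --- t -> z -----------------------------------------------------------------


def test_t_to_z_fixed_points():
    assert mr.t_to_z(np.array([0.0]), 4)[0] == 0.0
    assert mr.t_to_z(np.array([1.96]), math.inf)[0] == pytest.approx(1.96)
    assert mr.t_to_z(np.array([3.674]), 4)[0] == pytest.approx(2.302, abs=2e-3)


def test_t_to_z_monotone_and_odd():
    t = np.linspace(-30, 30, 401)
    z = mr.t_to_z(t, 7)
    assert np.all(np.diff(z) > 0)
    np.testing.assert_allclose(z, -mr.t_to_z(-t, 7), atol=1e-12)


def test_t_to_z_preserves_two_sided_p():
    # p-values of z and t agree to >= 6 digits over |z| <= 6
    t = np.array([0.1, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0])
    df = 10
    z = mr.t_to_z(t, df)
    assert np.all(np.abs(z) <= 6)
    p_t = 2 * st.t.sf(t, df)
    p_z = 2 * st.norm.sf(np.abs(z))
    np.testing.assert_allclose(p_z, p_t, rtol=1e-6)


def test_t_to_z_does_not_saturate_at_extreme_t():
    z = mr.t_to_z(np.array([1e4, 1e6]), 10)
    assert z[1] > z[0]
    assert np.all(np.isfinite(z))
    assert np.all(np.abs(z) <= 37)


# --- null calibration -------------------------------------------------------


def test_null_p_values_uniform():
    # no group effect, hierarchical variances: KS must not reject at 1%
    rng = np.random.default_rng(99)
    m, n1, n2, d0, s0_2 = 2000, 6, 6, 4.0, 0.04
    sigma = np.sqrt(s0_2 * d0 / rng.chisquare(d0, size=m))
    X = rng.normal(size=(m, n1 + n2)) * sigma[:, None]
    nm, samples = _nm(X[:, :n1], X[:, n1:])
    table, prior, _ = mr.differential_analysis(nm, samples)
    ks = st.kstest(table["p"], "uniform")
    assert ks.pvalue > 0.01
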