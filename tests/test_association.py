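"""Residual adjustment, per-marker regression (with a statsmodels
cross-check), inflation factors, permutation machinery and thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpacor.association import (
    adjust_betas,
    build_design,
    factor_pc_heatmap,
    genomic_inflation,
    marker_regression,
    permutation_null,
    residual_pcs,
    shuffle_markers,
    significance_threshold,
    two_stage_association,
)
from cpacor.data_model import BetaMatrix


def _beta(vals, offset=100.0):
    vals = np.asarray(vals, dtype=float)
    return BetaMatrix(pd.Index([f"m{i}" for i in range(vals.shape[0])]),
                      pd.Index([f"s{j}" for j in range(vals.shape[1])]),
                      vals, offset)


# ---------------------------------------------------------------------------
# adjust_betas / residual_pcs


def test_intercept_only_residuals_are_centred(rng):
    B = rng.random((20, 30)) * 0.9
    design = pd.DataFrame({"intercept": np.ones(30)},
                          index=[f"s{j}" for j in range(30)])
    res = adjust_betas(_beta(B), design)
    np.testing.assert_allclose(res.residuals, B - B.mean(axis=1, keepdims=True),
                               atol=1e-12)


def test_exact_linear_fit_leaves_zero_residuals(rng):
    age = rng.uniform(20, 80, size=40)
    B = np.clip(0.2 + 0.005 * age, 0, 0.999)[None, :].repeat(5, axis=0)
    design = pd.DataFrame({"intercept": np.ones(40), "age": age},
                          index=[f"s{j}" for j in range(40)])
    res = adjust_betas(_beta(B), design)
    np.testing.assert_allclose(res.residuals, 0.0, atol=1e-10)


def test_residuals_orthogonal_to_design(small_adjusted):
    res = adjust_betas(small_adjusted["beta"], small_adjusted["design"])
    X = small_adjusted["design"].to_numpy()
    R = np.nan_to_num(res.residuals)
    complete = ~np.isnan(res.residuals).any(axis=1)
    proj = R[complete] @ X
    scale = np.abs(R[complete]).sum(axis=1, keepdims=True) * np.abs(X).max(axis=0)
    assert (np.abs(proj) < 1e-6 * np.maximum(scale, 1e-30)).all()


def test_rank_deficient_design_names_columns(rng):
    B = rng.random((3, 10))
    x = rng.normal(size=10)
    design = pd.DataFrame({"intercept": np.ones(10), "a": x, "b": 2 * x},
                          index=[f"s{j}" for j in range(10)])
    with pytest.raises(ValueError, match="collinear"):
        adjust_betas(_beta(B), design)


def test_residual_pcs_exclude_missing_and_recover_factor(rng):
    n, m = 80, 300
    factor = rng.normal(size=n)
    load = rng.normal(size=m)
    R = np.outer(load, factor) * 0.02 + rng.normal(0, 0.005, size=(m, n))
    R[0, 0] = np.nan                                # marker 0 incomplete
    from cpacor.association import ResidualMatrix
    res = ResidualMatrix(pd.Index([f"m{i}" for i in range(m)]),
                         pd.Index([f"s{j}" for j in range(n)]), R, ["intercept"])
    pcs = residual_pcs(res, k=3)
    assert pcs.n_complete_markers == m - 1
    assert abs(np.corrcoef(pcs.scores["PC1"], factor)[0, 1]) > 0.9
    with pytest.raises(ValueError, match="complete markers"):
        residual_pcs(ResidualMatrix(res.marker_ids, res.sample_ids,
                                    np.full_like(R, np.nan), ["i"]), k=3)


# ---------------------------------------------------------------------------
# marker_regression


def test_logistic_wald_matches_statsmodels(rng):
    """Dual route: the in-package Newton solver reproduces statsmodels
    Logit coefficients, SEs and Wald p-values."""
    sm = pytest.importorskip("statsmodels.api")
    n, m = 150, 12
    B = rng.beta(0.5, 0.5, size=(m, n)).clip(1e-4, 1 - 1e-4) * 0.999
    age = rng.uniform(20, 80, size=n)
    y = (rng.random(n) < 0.5).astype(float)
    design = pd.DataFrame({"intercept": np.ones(n), "age": age},
                          index=[f"s{j}" for j in range(n)])
    res = marker_regression(y, _beta(B), design, family="logistic")
    for i in range(m):
        X = np.column_stack([B[i], design.to_numpy()])
        fit = sm.Logit(y, X).fit(disp=0)
        assert res.df["coef"].iloc[i] == pytest.approx(fit.params[0], abs=1e-6)
        assert res.df["se"].iloc[i] == pytest.approx(fit.bse[0], rel=1e-5)
        assert res.df["p"].iloc[i] == pytest.approx(fit.pvalues[0], abs=1e-6)


def test_logistic_contingency_table_log_odds(rng):
    """Dichotomous marker: the coefficient equals the closed-form log
    odds ratio log((n11 n00)/(n10 n01))."""
    x = np.array([1.0] * 40 + [0.0] * 60)
    y = np.array([1.0] * 30 + [0.0] * 10 + [1.0] * 20 + [0.0] * 40)
    res = marker_regression(y, _beta(0.5 * x[None, :] + 0.25), family="logistic")
    # beta values 0.75/0.25 -> coefficient on beta is log(OR)/0.5
    expected = np.log((30 * 40) / (10 * 20)) / 0.5
    assert res.df["coef"].iloc[0] == pytest.approx(expected, abs=1e-6)


def test_null_pvalues_uniform(rng):
    """Global null: 2,000 independent markers, random labels -> the p-value
    distribution is uniform (KS p > 0.01)."""
    n, m = 300, 2000
    B = rng.beta(0.5, 0.5, size=(m, n)) * 0.999
    y = (rng.random(n) < 0.5).astype(float)
    design = pd.DataFrame({"intercept": np.ones(n)},
                          index=[f"s{j}" for j in range(n)])
    res = adjust_betas(_beta(B), design)
    out = two_stage_association(res, y)
    p = out.df["p"].dropna().to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_no_association_gives_p_near_one(rng):
    """A marker whose case and control values mirror each other exactly has
    coefficient ~0 and p ~1."""
    vals = np.concatenate([np.linspace(0.2, 0.8, 20),
                           np.linspace(0.2, 0.8, 20)])
    y = np.array([1.0] * 20 + [0.0] * 20)
    res = marker_regression(y, _beta(vals[None, :]), family="logistic")
    assert abs(res.df["coef"].iloc[0]) < 1e-8
    assert res.df["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_linear_family_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    n = 80
    B = rng.random((5, n)) * 0.9
    y = rng.normal(size=n)
    z = rng.normal(size=n)
    design = pd.DataFrame({"intercept": np.ones(n), "z": z},
                          index=[f"s{j}" for j in range(n)])
    res = marker_regression(y, _beta(B), design, family="linear")
    for i in range(5):
        X = np.column_stack([B[i], design.to_numpy()])
        fit = sm.OLS(y, X).fit()
        assert res.df["coef"].iloc[i] == pytest.approx(fit.params[0], rel=1e-8)
        assert res.df["se"].iloc[i] == pytest.approx(fit.bse[0], rel=1e-8)
        assert res.df["p"].iloc[i] == pytest.approx(fit.pvalues[0], rel=1e-6)


# ---------------------------------------------------------------------------
# two-stage shortcut


def test_two_stage_agrees_with_direct_model(small_adjusted):
    """R^2 between -log10 p (and coefficients) of the residual shortcut and
    the direct fully adjusted model is near 1 even on a small fixture where
    the covariate count is a third of the sample size (the agreement at
    cohort scale is checked separately and is far tighter)."""
    beta = small_adjusted["beta"]
    design = small_adjusted["design"]
    y = small_adjusted["y"]
    direct = marker_regression(y, beta, design, family="logistic")
    res = adjust_betas(beta, design)
    short = two_stage_association(res, y, design=design)
    ok = (direct.df["converged"] & short.df["converged"]).to_numpy()
    lp_d = -np.log10(direct.df["p"].to_numpy()[ok])
    lp_s = -np.log10(short.df["p"].to_numpy()[ok])
    assert np.corrcoef(lp_d, lp_s)[0, 1] ** 2 > 0.99
    cd = direct.df["coef"].to_numpy()[ok]
    cs = short.df["coef"].to_numpy()[ok]
    assert np.corrcoef(cd, cs)[0, 1] ** 2 > 0.99


def test_two_stage_without_covariates_is_univariate(rng):
    """With an intercept-only design the shortcut equals the direct
    univariate logistic regression up to centring."""
    n = 100
    B = rng.beta(2, 2, size=(10, n)) * 0.99
    y = (rng.random(n) < 0.5).astype(float)
    design = pd.DataFrame({"intercept": np.ones(n)},
                          index=[f"s{j}" for j in range(n)])
    res = adjust_betas(_beta(B), design)
    short = two_stage_association(res, y)
    direct = marker_regression(y, _beta(B), design, family="logistic")
    np.testing.assert_allclose(short.df["coef"], direct.df["coef"], rtol=1e-6)
    np.testing.assert_allclose(short.df["p"], direct.df["p"], atol=1e-8)


# ---------------------------------------------------------------------------
# genomic inflation, permutation null, marker shuffle


def test_lambda_calibration_identities():
    n = 10_001
    grid = (np.arange(1, n + 1) - 0.5) / n
    assert genomic_inflation(grid) == pytest.approx(1.0, abs=0.01)
    assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0, abs=1e-12)


def test_lambda_monte_carlo_null(rng):
    z = rng.normal(size=10_000)
    p = 2 * stats.norm.sf(np.abs(z))
    assert 0.97 < genomic_inflation(p) < 1.03


def test_lambda_needs_enough_pvalues():
    with pytest.raises(ValueError):
        genomic_inflation([0.5] * 5)


def test_shuffle_markers_preserves_marginals_and_decorrelates(rng):
    n, m = 200, 120
    shared = rng.normal(size=n)
    B = np.clip(0.5 + 0.1 * shared[None, :] + 0.05 * rng.normal(size=(m, n)),
                0.001, 0.999)
    B[0, 5] = np.nan
    beta = BetaMatrix(pd.Index([f"m{i}" for i in range(m)]),
                      pd.Index([f"s{j}" for j in range(n)]), B)
    shuf = shuffle_markers(beta, seed=4)
    # per-marker multiset preserved exactly (NaN travels with values)
    for i in (0, 1, 50):
        a = np.sort(B[i][~np.isnan(B[i])])
        b = np.sort(shuf.beta[i][~np.isnan(shuf.beta[i])])
        np.testing.assert_array_equal(a, b)
    # inter-marker correlation collapses to O(n^-1/2)
    def mean_abs_corr(X):
        C = np.corrcoef(X)
        return np.abs(C[np.triu_indices_from(C, k=1)]).mean()
    before = mean_abs_corr(B[1:])
    after = mean_abs_corr(shuf.beta[1:])
    assert before > 0.5
    assert after < 3.0 / np.sqrt(n)
    # seeded determinism
    np.testing.assert_array_equal(shuffle_markers(beta, seed=4).beta, shuf.beta)


def test_permutation_null_calibrated_and_envelope_ordered(rng):
    n, m = 200, 800
    B = rng.beta(0.5, 0.5, size=(m, n)) * 0.999
    y = (rng.random(n) < 0.5).astype(float)
    design = pd.DataFrame({"intercept": np.ones(n)},
                          index=[f"s{j}" for j in range(n)])
    res = adjust_betas(_beta(B), design)
    ns = permutation_null(res, y, n_perm=60, seed=5)
    assert 0.95 < np.median(ns.lambdas) < 1.05
    assert (ns.envelope["lo"] <= ns.envelope["hi"]).all()
    assert ns.n_permutations == 60


def test_correlated_markers_widen_lambda_interval(rng):
    """A shared sample factor leaves the per-permutation lambda interval
    wider than for independent markers."""
    n, m = 200, 800
    shared = rng.normal(size=n)
    B = np.clip(0.5 + 0.15 * shared[None, :] + 0.03 * rng.normal(size=(m, n)),
                0.001, 0.999)
    y = (rng.random(n) < 0.5).astype(float)
    design = pd.DataFrame({"intercept": np.ones(n)},
                          index=[f"s{j}" for j in range(n)])
    beta = _beta(B)
    ns_corr = permutation_null(adjust_betas(beta, design), y, n_perm=60, seed=5)
    ns_ind = permutation_null(adjust_betas(shuffle_markers(beta, 1), design),
                              y, n_perm=60, seed=5)
    width_corr = ns_corr.lambda_q975 - ns_corr.lambda_q025
    width_ind = ns_ind.lambda_q975 - ns_ind.lambda_q025
    assert width_corr > width_ind


# ---------------------------------------------------------------------------
# threshold and heatmap


def test_significance_threshold_values():
    bonf, rounded = significance_threshold(470_000, alpha=0.05)
    assert bonf == pytest.approx(1.0638e-7, rel=1e-3)
    assert rounded == 1e-7
    assert significance_threshold(1)[0] == 0.05
    bonf2, rounded2 = significance_threshold(100)
    assert bonf2 == pytest.approx(5e-4)
    assert rounded2 == 1e-4


def test_factor_pc_heatmap(rng):
    n = 100
    pcs = pd.DataFrame(rng.normal(size=(n, 3)), columns=["PC1", "PC2", "PC3"],
                       index=[f"s{j}" for j in range(n)])
    cov = pd.DataFrame({
        "same_as_pc1": pcs["PC1"],
        "noise": rng.normal(size=n),
        "constant": np.ones(n),
    }, index=pcs.index)
    out = factor_pc_heatmap(pcs, cov)
    assert out.p_corrected.loc["PC1", "same_as_pc1"] < 1e-10
    assert out.neglog10.loc["PC1", "same_as_pc1"] > 10
    assert np.isnan(out.p_raw.loc["PC1", "constant"])
    # Bonferroni never decreases p
    raw = out.p_raw.to_numpy()
    corr = out.p_corrected.to_numpy()
    ok = ~np.isnan(raw)
    assert (corr[ok] >= raw[ok] - 1e-15).all()
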