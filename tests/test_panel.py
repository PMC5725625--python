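"""Panel estimators against independent least-squares oracles."""

import numpy as np
import pytest
from scipy import stats

import cyclecal as cc
from cyclecal import EstimationError, PanelDataset
from cyclecal.panel import (
    LinearFitResult,
    VarianceComponents,
    fit_panel,
    gls_random_effects,
    hausman_test,
    lsdv_fit,
    pooled_ols,
    variance_components,
)


def _panel(woman, x, y):
    woman = np.asarray(woman)
    ids, codes = np.unique(woman, return_inverse=True)
    return PanelDataset(
        woman=codes.astype(np.int64),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        ids=ids.astype(str),
    )


def _random_panel(rng, n_women=5, between=1.0):
    woman, x, y = [], [], []
    for i in range(n_women):
        t = int(rng.integers(2, 6))
        xi = rng.normal(30, 3, size=t)
        yi = 1.0 + 0.5 * xi + rng.normal(0, between) + rng.normal(0, 1, size=t)
        woman += [i] * t
        x += list(xi)
        y += list(yi)
    return _panel(woman, x, y)


# ---------------------------------------------------------------- pooled OLS

def test_pooled_ols_exact_line():
    p = _panel([0, 0, 1, 1], [1, 2, 3, 4], [5, 7, 9, 11])  # y = 3 + 2x
    fit = pooled_ols(p)
    assert fit.alpha == pytest.approx(3.0)
    assert fit.beta == pytest.approx(2.0)
    assert np.allclose(fit.resid, 0.0)


def test_pooled_ols_hand_example():
    p = _panel([0, 0, 0], [1, 2, 3], [1, 2, 2])
    fit = pooled_ols(p)
    assert fit.beta == pytest.approx(0.5)
    assert fit.alpha == pytest.approx(2.0 / 3.0)


def test_pooled_ols_residuals_orthogonal_to_design():
    rng = np.random.default_rng(0)
    p = _random_panel(rng)
    fit = pooled_ols(p)
    assert abs(fit.resid.sum()) < 1e-8
    assert abs((fit.resid * p.x).sum()) < 1e-8


def test_pooled_ols_singular_design():
    with pytest.raises(EstimationError):
        pooled_ols(_panel([0, 0], [5, 5], [1, 2]))


# ----------------------------------------------------------------- LSDV

def test_lsdv_exact_per_woman_lines():
    woman, x, y = [], [], []
    for i in (1, 2, 3):
        for xv in (1.0, 2.0, 3.0, 4.0):
            woman.append(i)
            x.append(xv)
            y.append(5.0 * i + 2.0 * xv)
    fit = lsdv_fit(_panel(woman, x, y))
    assert fit.beta == pytest.approx(2.0)
    for i in (1, 2, 3):
        assert fit.per_woman_alpha[str(i)] == pytest.approx(5.0 * i)


def test_lsdv_matches_dummy_expanded_least_squares():
    rng = np.random.default_rng(1)
    p = _random_panel(rng, n_women=3)
    fit = lsdv_fit(p)
    dummies = np.zeros((p.n_obs, p.n_women))
    dummies[np.arange(p.n_obs), p.woman] = 1.0
    design = np.column_stack([dummies, p.x])
    coef, *_ = np.linalg.lstsq(design, p.y, rcond=None)
    assert fit.beta == pytest.approx(coef[-1], rel=1e-10)
    for code, wid in enumerate(p.ids):
        assert fit.per_woman_alpha[wid] == pytest.approx(coef[code], rel=1e-10)


def test_lsdv_agrees_with_statsmodels_ols():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    p = _random_panel(rng, n_women=6)
    dummies = np.zeros((p.n_obs, p.n_women))
    dummies[np.arange(p.n_obs), p.woman] = 1.0
    res = sm.OLS(p.y, np.column_stack([dummies, p.x])).fit()
    assert lsdv_fit(p).beta == pytest.approx(res.params[-1], rel=1e-8)


def test_lsdv_invariant_to_per_woman_shifts():
    rng = np.random.default_rng(2)
    p = _random_panel(rng)
    shifted_y = p.y + 100.0 * (p.woman + 1)
    p2 = PanelDataset(woman=p.woman, x=p.x, y=shifted_y, ids=p.ids)
    assert lsdv_fit(p2).beta == pytest.approx(lsdv_fit(p).beta, rel=1e-10)


def test_lsdv_singular_without_within_variation():
    with pytest.raises(EstimationError):
        lsdv_fit(_panel([0, 0, 1, 1], [2, 2, 7, 7], [1, 2, 3, 4]))


# -------------------------------------------------------- variance components

def test_variance_components_zero_residuals():
    p = _panel([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
    vc = variance_components(p, np.zeros(6))
    assert (vc.sigma2_total, vc.sigma2_between, vc.sigma2_within) == (0.0, 0.0, 0.0)


def test_variance_components_recover_generative_variances():
    p = cc.recovery_panel(0.0, 0.5, sigma_alpha=1.0, sigma_eps=1.0, n_women=3000, t_obs=5, seed=8)
    vc = variance_components(p, pooled_ols(p).resid)
    assert vc.sigma2_between == pytest.approx(1.0, abs=0.1)
    assert vc.sigma2_within == pytest.approx(1.0, abs=0.1)


def test_variance_components_vanish_without_woman_effect():
    p = cc.recovery_panel(0.0, 0.5, sigma_alpha=0.0, sigma_eps=1.0, n_women=3000, t_obs=5, seed=9)
    vc = variance_components(p, pooled_ols(p).resid)
    assert abs(vc.sigma2_between) < 0.05


def test_variance_components_insufficient_data():
    p = _panel([0, 1, 2], [1, 2, 3], [1, 2, 3])  # no within-woman pairs
    with pytest.raises(EstimationError):
        variance_components(p, np.zeros(3))


# ------------------------------------------------------------------- GLS

def test_gls_reduces_to_pooled_when_between_is_zero():
    rng = np.random.default_rng(3)
    p = _random_panel(rng)
    comp = VarianceComponents(1.0, 0.0, 1.0)
    gls = gls_random_effects(p, comp)
    ols = pooled_ols(p)
    assert gls.alpha == pytest.approx(ols.alpha, rel=1e-12)
    assert gls.beta == pytest.approx(ols.beta, rel=1e-12)


def test_gls_matches_explicit_omega_normal_equations():
    """Quasi-demeaned GLS equals brute-force (X' Omega^-1 X)^-1 X' Omega^-1 y."""
    rng = np.random.default_rng(4)
    for n_women in (2, 5):
        p = _random_panel(rng, n_women=n_women)
        comp = VarianceComponents(3.0, 1.3, 1.7)
        gls = gls_random_effects(p, comp)
        # independent oracle: assemble the full block-diagonal covariance
        blocks = []
        for i in range(p.n_women):
            t = int(np.sum(p.woman == i))
            blocks.append(comp.sigma2_within * np.eye(t) + comp.sigma2_between * np.ones((t, t)))
        order = np.argsort(p.woman, kind="stable")
        omega = np.zeros((p.n_obs, p.n_obs))
        pos = 0
        for blk in blocks:
            t = blk.shape[0]
            omega[pos : pos + t, pos : pos + t] = blk
            pos += t
        X = np.column_stack([np.ones(p.n_obs), p.x[order]])
        y = p.y[order]
        oi = np.linalg.inv(omega)
        coef = np.linalg.solve(X.T @ oi @ X, X.T @ oi @ y)
        assert gls.alpha == pytest.approx(coef[0], rel=1e-8)
        assert gls.beta == pytest.approx(coef[1], rel=1e-8)


def test_gls_approaches_within_slope_as_between_dominates():
    rng = np.random.default_rng(5)
    p = _random_panel(rng)
    within_beta = lsdv_fit(p).beta
    comp = VarianceComponents(1e8 + 1.0, 1e8, 1.0)
    gls = gls_random_effects(p, comp)
    assert gls.beta == pytest.approx(within_beta, abs=1e-4)


def test_gls_degenerate_covariance():
    p = _panel([0, 0], [1, 2], [1, 2])
    with pytest.raises(EstimationError):
        gls_random_effects(p, VarianceComponents(1.0, 1.0, 0.0))


def test_all_estimators_recover_generative_coefficients():
    alpha, beta = 2.0, 0.4
    ests = {"pooled_ols": [], "lsdv": [], "gls_re": []}
    rng = np.random.default_rng(6)
    for _ in range(30):
        p = cc.recovery_panel(alpha, beta, sigma_alpha=0.7, sigma_eps=1.0, n_women=200, t_obs=6, seed=rng)
        for name, acc in ests.items():
            acc.append(fit_panel(p, name).beta)
    for name, betas in ests.items():
        assert np.mean(betas) == pytest.approx(beta, abs=0.01), name


# ----------------------------------------------------------------- Hausman

def _fit(estimator, beta):
    return LinearFitResult(estimator, 0.0, beta, np.zeros(1))


def test_hausman_identical_slopes():
    res = hausman_test(_fit("lsdv", 0.5), _fit("gls_re", 0.5))
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_hausman_chi2_quantile():
    h = stats.chi2.ppf(0.95, df=1)  # 3.841...
    res = hausman_test(_fit("lsdv", 0.0), _fit("gls_re", np.sqrt(h)))
    assert res.statistic == pytest.approx(3.841, abs=5e-4)
    assert res.p_value == pytest.approx(0.05, abs=1e-6)


def test_hausman_decision_rules():
    small_gap = hausman_test(_fit("lsdv", 0.5), _fit("gls_re", 0.5001))
    assert small_gap.p_value > 0.05 and small_gap.favored_model == "fixed"
    standard = hausman_test(_fit("lsdv", 0.5), _fit("gls_re", 0.5001), rule="standard")
    assert standard.favored_model == "random"
    with pytest.raises(cc.ConfigError):
        hausman_test(_fit("lsdv", 0.5), _fit("gls_re", 0.5), rule="bogus")


def test_hausman_small_under_random_effect_truth():
    rng = np.random.default_rng(10)
    stats_h = []
    for _ in range(20):
        p = cc.recovery_panel(1.0, 0.3, sigma_alpha=0.5, sigma_eps=1.0, n_women=300, t_obs=6, seed=rng)
        res = hausman_test(lsdv_fit(p), gls_random_effects(p))
        stats_h.append(res.statistic)
    assert np.median(stats_h) < 0.01
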