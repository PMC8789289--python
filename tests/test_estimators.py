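"""Causal estimators against independent oracles and their invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import interpolate, optimize

from adipomr.estimators import (
    DegenerateDesignError,
    EmptyInstrumentError,
    InsufficientInstrumentsError,
    egger,
    i2_gx,
    ivw,
    ratio_estimates,
    weighted_median,
)
from conftest import make_dataset


# ---------------------------------------------------------------- Wald ratios
@pytest.mark.parametrize(
    "gamma, Gamma, se_Gamma, ratio, ratio_se",
    [
        (0.5, 0.10, 0.02, 0.20, 0.04),
        (-0.5, 0.10, 0.02, -0.20, 0.04),
    ],
)
def test_ratio_estimates_arithmetic(gamma, Gamma, se_Gamma, ratio, ratio_se):
    data = make_dataset([gamma], [Gamma], [se_Gamma])
    [(vid, r, rse)] = ratio_estimates(data)
    assert r == pytest.approx(ratio) and rse == pytest.approx(ratio_se)


def test_ratio_estimates_proportional_case():
    gamma = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    data = make_dataset(gamma, 0.3 * gamma, np.full(5, 0.01))
    ratios = [r for _, r, _ in ratio_estimates(data)]
    assert ratios == pytest.approx([0.3] * 5)


# ------------------------------------------------------------------------ IVW
def test_ivw_single_variant_is_wald_ratio():
    est = ivw(make_dataset([0.5], [0.10], [0.02]))
    assert est.method == "wald_ratio"
    assert est.beta == pytest.approx(0.20) and est.se == pytest.approx(0.04)
    assert est.Q is None and est.I2 is None


def test_ivw_zero_residual_case():
    gamma = np.array([0.1, 0.25, 0.4])
    est = ivw(make_dataset(gamma, 0.3 * gamma, [0.02, 0.03, 0.04]))
    assert est.beta == pytest.approx(0.30)
    assert est.Q == pytest.approx(0.0, abs=1e-24)
    assert est.I2 == 0.0 and est.Q_df == 2


def test_ivw_matches_closed_form_oracle():
    """Direct evaluation of sum(w g G)/sum(w g^2) and its fixed SE."""
    gamma = [0.4, 0.2, 0.6]
    Gamma = [0.12, 0.05, 0.21]
    se_G = [0.02, 0.03, 0.04]
    w = [s**-2 for s in se_G]
    beta_oracle = sum(wi * g * G for wi, g, G in zip(w, gamma, Gamma)) / sum(
        wi * g * g for wi, g in zip(w, gamma)
    )
    se_oracle = sum(wi * g * g for wi, g in zip(w, gamma)) ** -0.5
    Q_oracle = sum(
        wi * (G - beta_oracle * g) ** 2 for wi, g, G in zip(w, gamma, Gamma)
    )
    est = ivw(make_dataset(gamma, Gamma, se_G), variance_model="fixed")
    assert est.beta == pytest.approx(beta_oracle, rel=1e-12)
    assert est.se == pytest.approx(se_oracle, rel=1e-12)
    assert est.Q == pytest.approx(Q_oracle, rel=1e-12)


def test_ivw_matches_weighted_origin_regression():
    """IVW equals WLS of Gamma on gamma through the origin (statsmodels)."""
    rng = np.random.default_rng(7)
    gamma = rng.uniform(0.05, 0.4, 12)
    se_G = rng.uniform(0.01, 0.05, 12)
    Gamma = 0.25 * gamma + se_G * rng.standard_normal(12)
    fit = sm.WLS(Gamma, gamma[:, None], weights=se_G**-2).fit()
    est = ivw(make_dataset(gamma, Gamma, se_G), variance_model="fixed")
    assert est.beta == pytest.approx(fit.params[0], rel=1e-10)


def test_ivw_multiplicative_random_inflates_se_only_upward():
    rng = np.random.default_rng(3)
    gamma = rng.uniform(0.05, 0.4, 20)
    se_G = np.full(20, 0.01)
    Gamma = 0.25 * gamma + 0.05 * rng.standard_normal(20)  # overdispersed
    fixed = ivw(make_dataset(gamma, Gamma, se_G), variance_model="fixed")
    rand = ivw(make_dataset(gamma, Gamma, se_G), variance_model="multiplicative_random")
    assert rand.beta == fixed.beta
    assert rand.se == pytest.approx(fixed.se * max(1, fixed.Q / fixed.Q_df) ** 0.5)
    assert rand.se >= fixed.se


def test_ivw_empty_raises():
    with pytest.raises(EmptyInstrumentError):
        ivw(make_dataset([], [], []))


# -------------------------------------------------------------------- MR-Egger
def test_egger_exact_fit_recovers_intercept_and_slope():
    gamma = np.array([0.1, 0.2, 0.3, 0.5])
    data = make_dataset(gamma, 0.05 + 0.3 * gamma, np.full(4, 0.02))
    est = egger(data)
    assert est.intercept == pytest.approx(0.05, rel=1e-10)
    assert est.beta == pytest.approx(0.30, rel=1e-10)
    assert est.Q == pytest.approx(0.0, abs=1e-20)
    assert est.Q_df == 2


def test_egger_null_case():
    gamma = np.array([0.1, 0.2, 0.4])
    est = egger(make_dataset(gamma, np.zeros(3), np.full(3, 0.02)))
    assert est.beta == pytest.approx(0.0, abs=1e-15)
    assert est.intercept == pytest.approx(0.0, abs=1e-15)


def test_egger_matches_normal_equations_oracle():
    """Slope/intercept/SEs from an independently assembled WLS solve."""
    gamma = np.array([0.15, 0.3, 0.45, 0.6])
    Gamma = np.array([0.07, 0.1, 0.16, 0.2])
    se_G = np.array([0.02, 0.025, 0.03, 0.02])
    W = np.diag(se_G**-2.0)
    X = np.column_stack([np.ones(4), gamma])
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ Gamma)
    cov = np.linalg.inv(XtWX)
    resid = Gamma - X @ coef
    Q = float(resid @ W @ resid)
    infl = max(1.0, Q / 2) ** 0.5  # df = L - 2 = 2, multiplicative random
    est = egger(make_dataset(gamma, Gamma, se_G))
    assert est.intercept == pytest.approx(coef[0], rel=1e-10)
    assert est.beta == pytest.approx(coef[1], rel=1e-10)
    assert est.intercept_se == pytest.approx(cov[0, 0] ** 0.5 * infl, rel=1e-10)
    assert est.se == pytest.approx(cov[1, 1] ** 0.5 * infl, rel=1e-10)
    assert est.Q == pytest.approx(Q, rel=1e-10)
    # statsmodels point estimates as a second, independent route
    fit = sm.WLS(Gamma, X, weights=se_G**-2.0).fit()
    assert est.intercept == pytest.approx(fit.params[0], rel=1e-10)
    assert est.beta == pytest.approx(fit.params[1], rel=1e-10)


def test_egger_requires_three_instruments_and_distinct_gamma():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_dataset([0.1, 0.2], [0.03, 0.06], [0.02, 0.02]))
    with pytest.raises(DegenerateDesignError):
        egger(make_dataset([0.2, 0.2, -0.2], [0.05, 0.06, -0.05], [0.02] * 3))


# ------------------------------------------------------------- weighted median
def test_weighted_median_equal_weights_hits_middle():
    gamma = np.ones(3)
    Gamma = np.array([0.1, 0.2, 0.7])
    est = weighted_median(make_dataset(gamma, Gamma, np.full(3, 0.02)), seed=0)
    assert est.beta == pytest.approx(0.2)


def test_weighted_median_constant_ratios():
    gamma = np.array([0.1, 0.3, 0.5, 0.2])
    est = weighted_median(
        make_dataset(gamma, 0.3 * gamma, [0.01, 0.05, 0.02, 0.04]), seed=0
    )
    assert est.beta == pytest.approx(0.3)


def test_weighted_median_matches_grid_oracle():
    """50% point of the interpolated weighted empirical CDF, solved by root
    finding on a dense piecewise-linear representation."""
    ratios = np.array([0.0, 0.1, 0.3, 0.4])
    rel_w = np.array([1.0, 1.0, 3.0, 1.0])
    # encode weights through se: w = ratio_se^-2, gamma = 1 so ratio = Gamma
    se_G = rel_w**-0.5
    data = make_dataset(np.ones(4), ratios, se_G)
    w = rel_w / rel_w.sum()
    p = np.cumsum(w) - w / 2
    cdf = interpolate.interp1d(ratios, p, fill_value="extrapolate")
    oracle = optimize.brentq(lambda v: cdf(v) - 0.5, 0.0, 0.4, xtol=1e-14)
    est = weighted_median(data, seed=0)
    assert est.beta == pytest.approx(oracle, abs=1e-12)
    assert est.beta == pytest.approx(0.25)  # hand-computed interpolation


def test_weighted_median_bootstrap_deterministic():
    rng = np.random.default_rng(11)
    gamma = rng.uniform(0.05, 0.4, 10)
    Gamma = 0.2 * gamma + 0.01 * rng.standard_normal(10)
    data = make_dataset(gamma, Gamma, np.full(10, 0.01))
    a = weighted_median(data, n_boot=500, seed=42)
    b = weighted_median(data, n_boot=500, seed=42)
    c = weighted_median(data, n_boot=500, seed=43)
    assert a.se == b.se and a.beta == b.beta
    assert a.se != c.se


def test_weighted_median_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        weighted_median(make_dataset([0.1, 0.2], [0.03, 0.06], [0.02] * 2), seed=0)


# ------------------------------------------------------------------ invariances
@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.floats(0.1, 10), st.integers(0, 2**31 - 1))
def test_scale_equivariance(c, seed):
    """Scaling all Gamma and se_Gamma by c scales every beta and se by c."""
    rng = np.random.default_rng(seed)
    L = 8
    gamma = rng.uniform(0.05, 0.4, L)
    se_G = rng.uniform(0.005, 0.03, L)
    Gamma = 0.2 * gamma + se_G * rng.standard_normal(L)
    base = make_dataset(gamma, Gamma, se_G)
    scaled = make_dataset(gamma, c * Gamma, c * se_G)
    for fn, kw in [(ivw, {}), (egger, {}), (weighted_median, {"seed": 5, "n_boot": 200})]:
        a, b = fn(base, **kw), fn(scaled, **kw)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-9, abs=1e-12)
        assert b.se == pytest.approx(c * a.se, rel=1e-9, abs=1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_orientation_invariance(seed):
    """Flipping (gamma_j, Gamma_j) sign pairs never changes the estimates."""
    rng = np.random.default_rng(seed)
    L = 9
    gamma = rng.uniform(0.05, 0.4, L)
    se_g = gamma / 8
    se_G = rng.uniform(0.005, 0.03, L)
    Gamma = 0.2 * gamma + se_G * rng.standard_normal(L)
    flip = rng.choice([-1.0, 1.0], L)
    base = make_dataset(gamma, Gamma, se_G, se_gamma=se_g)
    flipped = make_dataset(flip * gamma, flip * Gamma, se_G, se_gamma=se_g)
    assert ivw(flipped).beta == pytest.approx(ivw(base).beta, rel=1e-12)
    assert egger(flipped).beta == pytest.approx(egger(base).beta, rel=1e-12)
    assert egger(flipped).intercept == pytest.approx(egger(base).intercept, rel=1e-12)
    wm_a = weighted_median(base, n_boot=200, seed=9)
    wm_b = weighted_median(flipped, n_boot=200, seed=9)
    assert wm_b.beta == pytest.approx(wm_a.beta, rel=1e-12)


def test_estimators_consistent_as_noise_vanishes():
    """With no pleiotropy all three estimators converge to theta."""
    rng = np.random.default_rng(2)
    gamma = rng.uniform(0.05, 0.4, 20)
    theta = 0.35
    for scale in (1e-4, 1e-6):
        se_G = np.full(20, scale)
        Gamma = theta * gamma + se_G * rng.standard_normal(20)
        data = make_dataset(gamma, Gamma, se_G, se_gamma=np.full(20, 1e-8))
        assert ivw(data).beta == pytest.approx(theta, abs=20 * scale)
        assert egger(data).beta == pytest.approx(theta, abs=200 * scale)
        assert weighted_median(data, n_boot=200, seed=1).beta == pytest.approx(
            theta, abs=20 * scale
        )


def test_i2_gx_zero_for_equal_strength_and_large_for_spread():
    equal = make_dataset([0.2, 0.2, 0.2], [0.05, 0.06, 0.07], [0.02] * 3)
    # equal gamma: Q_GX = 0 (no spread)
    assert i2_gx(equal) == 0.0
    spread = make_dataset(
        [0.05, 0.2, 0.6], [0.01, 0.05, 0.2], [0.02] * 3, se_gamma=[0.005] * 3
    )
    assert 0.0 <= i2_gx(spread) <= 100.0
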