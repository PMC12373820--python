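"""Statistics engine: residualization, contrasts, odds, adjustment."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ctdose.exceptions import NumericalError
from ctdose.stats import (CovariateResidualizer, bonferroni, comorbidity_odds,
                          hedges_g, residualize, responder_threshold,
                          response_odds, welch_t)

# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------


def _covariate_data(rng, n=5000):
    age = rng.uniform(18, 90, n)
    gender = rng.choice(["male", "female", "not_reported"], size=n,
                        p=[0.4, 0.5, 0.1])
    return age, gender


def test_residuals_zero_for_exact_linear_trend(rng):
    age, gender = _covariate_data(rng, 500)
    outcome = 3.0 + 2.0 * age
    resid, model = residualize(outcome, age, gender)
    assert np.max(np.abs(resid)) < 1e-8
    assert abs(resid.sum()) < 1e-8


def test_residuals_sum_to_zero_on_fit_population(rng):
    age, gender = _covariate_data(rng, 1000)
    outcome = rng.normal(0, 5, 1000)
    resid, _ = residualize(outcome, age, gender)
    assert abs(resid.sum()) < 1e-8


def test_residual_sd_recovers_noise_scale(rng):
    age, gender = _covariate_data(rng)
    outcome = (2.0 * age - 0.01 * age**2
               + 1.5 * (gender == "female") + rng.normal(0, 1, len(age)))
    resid, _ = residualize(outcome, age, gender)
    assert abs(resid.std(ddof=1) - 1.0) < 0.05


def test_model_applies_to_subsets(rng):
    age, gender = _covariate_data(rng, 2000)
    outcome = 0.5 * age + rng.normal(0, 1, 2000)
    _, model = residualize(outcome, age, gender, fit_population="all")
    sub = slice(0, 300)
    sub_resid = model.residuals(outcome[sub], age[sub], gender[sub])
    # same coefficients, so subset residuals equal the slice of full residuals
    full_resid = model.residuals(outcome, age, gender)
    assert np.allclose(sub_resid, full_resid[sub])


def test_rank_deficient_design_names_terms(rng):
    age = np.full(200, 50.0)        # constant age collides with the intercept
    gender = np.array(["male"] * 200, dtype=object)
    with pytest.raises(NumericalError, match="collinear"):
        residualize(rng.normal(size=200), age, gender)


def test_sklearn_style_residualizer(rng):
    import pandas as pd

    age, gender = _covariate_data(rng, 1500)
    X = pd.DataFrame({"age": age, "gender": gender})
    y = 1.0 + 0.3 * age + rng.normal(0, 2, 1500)
    est = CovariateResidualizer().fit(X, y)
    assert est.get_params()["fit_population"] == "all"
    resid = est.residuals(X, y)
    assert abs(resid.mean()) < 1e-10
    ref, _ = residualize(y, age, gender)
    assert np.allclose(resid, ref)


# ---------------------------------------------------------------------------
# Welch t and Hedges g
# ---------------------------------------------------------------------------


def test_welch_identical_groups():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_hand_computed_example():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0, 7.0])
    # independent hand computation of the Welch formula
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / 3 + vb / 4
    t_hand = (a.mean() - b.mean()) / math.sqrt(se2)
    df_hand = se2**2 / ((va / 3) ** 2 / 2 + (vb / 4) ** 2 / 3)
    t, df, p = welch_t(a, b)
    assert t == pytest.approx(t_hand, abs=1e-12)
    assert df == pytest.approx(df_hand, abs=1e-12)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand), abs=1e-12)


def test_welch_reduces_to_pooled_df_for_equal_variances(rng):
    a = np.array([0.0, 1.0, 2.0, 3.0])
    b = a + 10.0                    # identical variances, equal n
    _, df, _ = welch_t(a, b)
    assert df == pytest.approx(2 * len(a) - 2, abs=1e-6)


def test_hedges_correction_example():
    # n=10 each, mean difference 1, pooled SD exactly 1
    d = math.sqrt(0.9)
    a = np.array([1 - d, 1 + d] * 5)
    b = np.array([-d, d] * 5)
    g, (lo, hi) = hedges_g(a, b)
    J = 1 - 3 / (4 * 20 - 9)
    assert g == pytest.approx(J, abs=1e-12)
    assert lo < g < hi


def test_hedges_antisymmetry_and_zero(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 40)
    g_ab, _ = hedges_g(a, b)
    g_ba, _ = hedges_g(b, a)
    assert g_ab == pytest.approx(-g_ba, abs=1e-12)
    g_same, _ = hedges_g(a, a)
    assert g_same == 0.0


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


def test_bonferroni_rules():
    assert bonferroni(0.01, 8) == pytest.approx(0.08)
    assert bonferroni(0.5, 4) == 1.0
    assert bonferroni(0.2, 1) == pytest.approx(0.2)
    with pytest.raises(NumericalError):
        bonferroni(1.5, 2)


# ---------------------------------------------------------------------------
# Comorbidity odds
# ---------------------------------------------------------------------------


def test_comorbidity_null_simulation(rng):
    n = 50_000
    adhd = rng.random(n) < 0.15
    cond = rng.random(n) < 0.2          # independent of ADHD
    age, gender = _covariate_data(rng, n)
    est = comorbidity_odds(cond, adhd, age, gender)
    assert 0.9 <= est.estimate <= 1.1
    assert est.ci_low <= est.estimate <= est.ci_high


def test_comorbidity_recovers_injected_log_or(rng):
    n = 30_000
    adhd = rng.random(n) < 0.2
    p = 1 / (1 + np.exp(-(-1.5 + math.log(2.0) * adhd)))
    cond = rng.random(n) < p
    age, gender = _covariate_data(rng, n)
    est = comorbidity_odds(cond, adhd, age, gender)
    assert est.ci_low <= 2.0 <= est.ci_high


def test_comorbidity_degenerate_errors(rng):
    age, gender = _covariate_data(rng, 100)
    with pytest.raises(NumericalError, match="constant"):
        comorbidity_odds(rng.random(100) < 0.5, np.ones(100, bool), age, gender)
    with pytest.raises(NumericalError, match="single outcome"):
        comorbidity_odds(np.zeros(100, bool), rng.random(100) < 0.5, age, gender)


# ---------------------------------------------------------------------------
# Responder analysis
# ---------------------------------------------------------------------------


def test_responder_threshold_arithmetic(rng):
    baseline = rng.normal(100, 14, 5000)
    thr = responder_threshold(baseline)
    assert thr == pytest.approx(0.5 * baseline.std(ddof=1))
    assert responder_threshold(baseline + 50) == pytest.approx(thr)        # location
    assert responder_threshold(baseline * 2) == pytest.approx(2 * thr)     # scale


def test_response_odds_contingency_arithmetic():
    # low 10/50 responders, high 25/50 -> odds 0.25 and 1.0, OR 4.0
    thr = 5.0
    low = np.array([6.0] * 10 + [0.0] * 40)
    high = np.array([6.0] * 25 + [0.0] * 25)
    res = response_odds(low, high, thr)
    assert res.odds_low == pytest.approx(10 / 40, abs=1e-12)
    assert res.odds_high == pytest.approx(1.0, abs=1e-12)
    assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)
    assert res.odds_ratio_ci[0] < 4.0 < res.odds_ratio_ci[1]


def test_response_odds_identical_strata_or_one():
    thr = 1.0
    x = np.array([2.0] * 20 + [0.0] * 20)
    res = response_odds(x, x.copy(), thr)
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)


def test_response_odds_unbounded_flag():
    res = response_odds(np.zeros(10), np.full(10, 9.0), 5.0)
    assert res.unbounded_ci
    assert res.odds_ratio_ci == (0.0, float("inf"))
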