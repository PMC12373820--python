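"""Statistical machinery for the dose-response analysis.

Covers covariate residualization of change scores (age + age^2 + gender),
Welch two-sample tests, Hedges g with the small-sample correction
J = 1 - 3/(4N - 9), covariate-adjusted comorbidity odds via logistic
regression, the distribution-based clinically-meaningful-responder analysis
(threshold = 1/2 SD of cohort baseline scores), and Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import NumericalError

GENDER_LEVELS = ("male", "female", "not_reported")   # male is reference


@dataclass
class EffectEstimate:
    """Point estimate + CI + test statistics for one contrast."""

    measure_id: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    statistic_type: str          # "t" | "z" | "chi2"
    df: float
    p_raw: float
    p_adjusted: float | None = None
    family: str | None = None
    n_per_group: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "measure_id": self.measure_id, "contrast": self.contrast,
            "estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "statistic": self.statistic, "statistic_type": self.statistic_type,
            "df": self.df, "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "family": self.family, "n_per_group": self.n_per_group,
        }


@dataclass
class ResponderResult:
    """Per-stratum responder odds and the between-dose odds ratio."""

    measure_id: str
    threshold: float
    odds_low: float
    odds_low_ci: tuple[float, float]
    odds_high: float
    odds_high_ci: tuple[float, float]
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    n_responders: dict[str, int] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    unbounded_ci: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "measure_id": self.measure_id, "threshold": self.threshold,
            "odds_low": self.odds_low, "odds_low_ci": list(self.odds_low_ci),
            "odds_high": self.odds_high, "odds_high_ci": list(self.odds_high_ci),
            "odds_ratio": self.odds_ratio, "odds_ratio_ci": list(self.odds_ratio_ci),
            "n_responders": self.n_responders, "n_per_group": self.n_per_group,
            "unbounded_ci": self.unbounded_ci,
        }


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------

def covariate_design(age, gender, center: float = 0.0) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + age + age^2 + gender dummies (male ref)."""
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=object)
    cols = [np.ones(len(age)), age - center, (age - center) ** 2]
    names = ["intercept", "age", "age_sq"]
    for level in GENDER_LEVELS[1:]:
        cols.append((gender == level).astype(float))
        names.append(f"gender_{level}")
    return np.column_stack(cols), names


@dataclass
class CovariateModel:
    """Least-squares fit of an outcome on age, age^2, and gender."""

    coefficients: dict[str, float]
    fit_population: str
    n_fit: int
    age_center: float = 0.0

    def predict(self, age, gender) -> np.ndarray:
        X, names = covariate_design(age, gender, self.age_center)
        beta = np.array([self.coefficients[n] for n in names])
        return X @ beta

    def residuals(self, outcome, age, gender) -> np.ndarray:
        return np.asarray(outcome, dtype=float) - self.predict(age, gender)


def residualize(outcome, age, gender, fit_population: str = "all",
                min_obs_per_coef: int = 10) -> tuple[np.ndarray, CovariateModel]:
    """Fit outcome ~ age + age^2 + gender by least squares and return the
    residuals on the fitted population plus the reusable model.

    The model is meant to be fitted once on all twice-tested participants,
    then applied (via ``CovariateModel.residuals``) to any subset.
    """
    outcome = np.asarray(outcome, dtype=float)
    if np.isnan(outcome).any():
        raise NumericalError("residualize: outcome contains NaN")
    center = float(np.mean(np.asarray(age, dtype=float)))
    X, names = covariate_design(age, gender, center)
    # drop gender dummies absent from the data before checking rank
    keep = [i for i, n in enumerate(names)
            if not n.startswith("gender_") or X[:, i].any()]
    X_used, names_used = X[:, keep], [names[i] for i in keep]
    if len(outcome) < min_obs_per_coef * X_used.shape[1]:
        raise NumericalError(
            f"residualize: need >= {min_obs_per_coef} observations per coefficient "
            f"({X_used.shape[1]} coefficients, {len(outcome)} observations)")
    rank = np.linalg.matrix_rank(X_used)
    if rank < X_used.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X_used, mode="economic", pivoting=True)
        dep = [names_used[piv[i]] for i in range(rank, X_used.shape[1])]
        raise NumericalError(f"residualize: design is rank-deficient; collinear terms: {dep}")
    beta, *_ = np.linalg.lstsq(X_used, outcome, rcond=None)
    coef = {n: 0.0 for n in names}
    coef.update(dict(zip(names_used, beta)))
    model = CovariateModel(coefficients=coef, fit_population=fit_population,
                           n_fit=len(outcome), age_center=center)
    return outcome - X_used @ beta, model


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper over :func:`residualize`.

    fit(X, y) with X a DataFrame holding ``age`` and ``gender`` columns and y
    the outcome; transform(X, y is passed via ``residuals``) returns
    residuals for any subset using the coefficients fitted on the fit
    population. Fitted attribute: ``model_`` (a CovariateModel).
    """

    def __init__(self, fit_population: str = "all", min_obs_per_coef: int = 10):
        self.fit_population = fit_population
        self.min_obs_per_coef = min_obs_per_coef

    def fit(self, X: pd.DataFrame, y):
        _, self.model_ = residualize(np.asarray(y, dtype=float),
                                     X["age"], X["gender"],
                                     fit_population=self.fit_population,
                                     min_obs_per_coef=self.min_obs_per_coef)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted covariate component for the rows of X."""
        return self.model_.predict(X["age"], X["gender"])

    def residuals(self, X: pd.DataFrame, y) -> np.ndarray:
        return self.model_.residuals(np.asarray(y, dtype=float), X["age"], X["gender"])


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-tailed p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise NumericalError("welch_t: each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 and vb <= 0:
        raise NumericalError("welch_t: both groups have zero variance")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hedges_g(group_a, group_b, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Hedges g (bias-corrected standardized mean difference) with CI.

    g = J * (mean_a - mean_b) / s_pooled,  J = 1 - 3 / (4 N - 9),  N = na+nb.
    The CI uses the standard large-sample variance
    var(g) = N/(na*nb) + g^2 / (2 (N - 2)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise NumericalError("hedges_g: each group needs n >= 2")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise NumericalError("hedges_g: zero pooled variance")
    N = na + nb
    J = 1.0 - 3.0 / (4.0 * N - 9.0)
    g = J * (a.mean() - b.mean()) / math.sqrt(sp2)
    var_g = N / (na * nb) + g**2 / (2.0 * (N - 2))
    z = sps.norm.ppf(0.5 + ci / 2.0)
    half = z * math.sqrt(var_g)
    return float(g), (float(g - half), float(g + half))


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni adjustment: p_adj = min(1, m * p).

    Aggregate measures form their own family of size 1 (identity)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise NumericalError("bonferroni: p values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise NumericalError("bonferroni: family size must be >= 1")
    adj = np.minimum(1.0, m * p)
    return float(adj) if np.isscalar(p_values) else adj


# ---------------------------------------------------------------------------
# Comorbidity odds
# ---------------------------------------------------------------------------

def comorbidity_odds(condition_flag, adhd_flag, age, gender,
                     ci: float = 0.95) -> EffectEstimate:
    """Covariate-adjusted odds ratio of reporting a condition given ADHD.

    Logistic regression: condition ~ ADHD + age + age^2 + gender; the OR is
    exp of the ADHD coefficient with a Wald CI.
    """
    y = np.asarray(condition_flag, dtype=float)
    adhd = np.asarray(adhd_flag, dtype=float)
    if len(np.unique(y)) < 2:
        raise NumericalError("comorbidity_odds: condition has a single outcome (no contrast)")
    if len(np.unique(adhd)) < 2:
        raise NumericalError("comorbidity_odds: ADHD flag is constant (no contrast)")
    center = float(np.mean(np.asarray(age, dtype=float)))
    X, names = covariate_design(age, gender, center)
    keep = [i for i, n in enumerate(names)
            if not n.startswith("gender_") or X[:, i].any()]
    X = np.column_stack([X[:, keep], adhd])
    names = [names[i] for i in keep] + ["adhd"]
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise NumericalError(f"comorbidity_odds: logistic fit failed ({exc}); "
                             "penalized fits are out of scope") from exc
    if (not np.isfinite(res.params).all() or not np.isfinite(res.bse).all()
            or np.max(np.abs(res.params)) > 20 or np.max(res.bse) > 1e3):
        raise NumericalError("comorbidity_odds: complete or quasi-complete separation; "
                             "penalized fits are out of scope")
    j = names.index("adhd")
    coef, se = res.params[j], res.bse[j]
    z = coef / se
    zq = sps.norm.ppf(0.5 + ci / 2.0)
    return EffectEstimate(
        measure_id="", contrast="adhd_plus_vs_minus",
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zq * se)), ci_high=float(np.exp(coef + zq * se)),
        statistic=float(z), statistic_type="z", df=float("inf"),
        p_raw=float(2.0 * sps.norm.sf(abs(z))),
        n_per_group={"adhd_plus": int(adhd.sum()), "adhd_minus": int(len(adhd) - adhd.sum())},
    )


# ---------------------------------------------------------------------------
# Clinically-meaningful-responder analysis
# ---------------------------------------------------------------------------

def responder_threshold(baseline_scores, sd_fraction: float = 0.5) -> float:
    """Distribution-based clinically-meaningful-change threshold:
    half the SD of the cohort's baseline scores (per measure)."""
    x = np.asarray(baseline_scores, dtype=float)
    if len(x) < 2:
        raise NumericalError("responder_threshold: need n >= 2 baseline scores")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise NumericalError("responder_threshold: zero baseline SD")
    return float(sd_fraction * sd)


def _odds_with_ci(r: int, n: int, zq: float) -> tuple[float, tuple[float, float], bool]:
    if r == 0 or r == n:
        odds = r / max(n - r, 1) if r else 0.0
        return odds, (0.0, float("inf")), True
    odds = r / (n - r)
    se = math.sqrt(1.0 / r + 1.0 / (n - r))
    return odds, (math.exp(math.log(odds) - zq * se), math.exp(math.log(odds) + zq * se)), False


def response_odds(change_low, change_high, threshold: float, measure_id: str = "",
                  ci: float = 0.95) -> ResponderResult:
    """Responder odds per dose stratum and the high-vs-low odds ratio.

    A responder improves from baseline by at least ``threshold``. Per-stratum
    odds are r/(n-r) with a log-odds normal CI; the OR comes from a logistic
    model of responder status on stratum (identical point estimate to the
    2x2 cross ratio). A stratum with 0 or all responders yields an unbounded
    CI and sets ``unbounded_ci``.
    """
    lo = np.asarray(change_low, dtype=float)
    hi = np.asarray(change_high, dtype=float)
    if len(lo) == 0 or len(hi) == 0:
        raise NumericalError("response_odds: both strata must be non-empty")
    if threshold <= 0:
        raise NumericalError("response_odds: threshold must be positive")
    zq = sps.norm.ppf(0.5 + ci / 2.0)
    r_lo, n_lo = int((lo >= threshold).sum()), len(lo)
    r_hi, n_hi = int((hi >= threshold).sum()), len(hi)
    odds_lo, ci_lo, unb_lo = _odds_with_ci(r_lo, n_lo, zq)
    odds_hi, ci_hi, unb_hi = _odds_with_ci(r_hi, n_hi, zq)
    if unb_lo or unb_hi:
        or_est = (odds_hi / odds_lo) if odds_lo > 0 else float("inf")
        or_ci = (0.0, float("inf"))
        unbounded = True
    else:
        y = np.concatenate([(lo >= threshold), (hi >= threshold)]).astype(float)
        x = np.column_stack([np.ones(n_lo + n_hi),
                             np.concatenate([np.zeros(n_lo), np.ones(n_hi)])])
        res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        coef, se = res.params[1], res.bse[1]
        or_est = float(np.exp(coef))
        or_ci = (float(np.exp(coef - zq * se)), float(np.exp(coef + zq * se)))
        unbounded = False
    return ResponderResult(
        measure_id=measure_id, threshold=float(threshold),
        odds_low=float(odds_lo), odds_low_ci=ci_lo,
        odds_high=float(odds_hi), odds_high_ci=ci_hi,
        odds_ratio=or_est, odds_ratio_ci=or_ci,
        n_responders={"low": r_lo, "high": r_hi},
        n_per_group={"low": n_lo, "high": n_hi},
        unbounded_ci=unbounded)


# ---------------------------------------------------------------------------
# Minor helpers
# ---------------------------------------------------------------------------

def gender_chisq(gender_a, gender_b) -> tuple[float, float, float]:
    """Chi-square test of gender composition between two groups
    (used for the dose-group demographics table)."""
    a = pd.Series(gender_a).value_counts()
    b = pd.Series(gender_b).value_counts()
    table = pd.concat([a, b], axis=1).fillna(0.0).to_numpy().T
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, dof, _ = sps.chi2_contingency(table)
    return float(chi2), float(dof), float(p)
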