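"""Synthetic cohort generator.

Emulates the statistical structure of a real-world cognitive-training study
cohort: an ADHD (self-reported lifetime diagnosis) subgroup that is younger
and more often male than the rest, ADHD-linked psychiatric comorbidity odds,
baseline performance deficits on an 8-subtest neurocognitive battery and a
7-item attention/mood scale, retest (practice) gains on the performance
battery but not on self-report, and a training effect that grows with the
log of intervening gameplay dose. Ground truth is written to a side table
consumed only by tests, never by the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .config import (
    AGE_BINS,
    ATTENTION_ITEMS,
    BAMS_ITEMS,
    EDUCATION_LEVELS,
    GENDERS,
    MOOD_ITEMS,
    NCPT_SUBTESTS,
    GeneratorConfig,
    load_condition_lists,
)
from .exceptions import ConfigurationError
from .bams import load_item_map

# Shared-trait loadings for the scale items; chosen so 4 attention items give
# an internal consistency (Cronbach alpha) near 0.72 and 3 mood items near
# 0.75, matching typical brief self-report subscales.
ATTENTION_ITEM_LOADING = 0.63
MOOD_ITEM_LOADING = 0.70

# Equal-probability quintile cuts for Likert discretization of a standard
# normal latent (0..4 with equal mass under the null).
_LIKERT_CUTS = norm.ppf([0.2, 0.4, 0.6, 0.8])

PARTICIPANT_COLUMNS = ["participant_id", "age", "gender", "education", "survey_completed"]
SESSION_COLUMNS = ["participant_id", "instrument", "session_index", "day",
                   "measure", "raw_score", "response_label"]
GAMEPLAY_COLUMNS = ["participant_id", "day", "n_plays"]


@dataclass
class SimulatedCohort:
    """Linked output tables plus the generator-internal ground truth."""

    participants: pd.DataFrame
    sessions: pd.DataFrame
    gameplays: pd.DataFrame
    ground_truth: pd.DataFrame

    def write_csv(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.participants.to_csv(os.path.join(outdir, "participants.csv"), index=False)
        self.sessions.to_csv(os.path.join(outdir, "sessions.csv"), index=False)
        self.gameplays.to_csv(os.path.join(outdir, "gameplays.csv"), index=False)
        self.ground_truth.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)


def _choice(rng: np.random.Generator, labels: list[str], probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draw with a stable label order."""
    cum = np.cumsum(probs)
    u = rng.random(n)
    idx = np.searchsorted(cum, u, side="right")
    idx = np.clip(idx, 0, len(labels) - 1)
    return np.asarray(labels, dtype=object)[idx]


def _truncated_ages(rng, mask, mean, sd, lo, hi, out):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    out[mask] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=int(mask.sum()), random_state=rng)


def generate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Generate linked participant, session, and gameplay tables.

    Deterministic for a fixed ``config.seed``: two calls with equal configs
    produce bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    conditions, _ = load_condition_lists()
    extra_conditions = [c for c in config.comorbidity_log_odds if c not in conditions]
    all_conditions = conditions + extra_conditions

    if n == 0:
        participants = pd.DataFrame(columns=PARTICIPANT_COLUMNS + all_conditions)
        sessions = pd.DataFrame(columns=SESSION_COLUMNS)
        gameplays = pd.DataFrame(columns=GAMEPLAY_COLUMNS)
        gt_cols = (["participant_id", "adhd_true", "dose_stratum_intent",
                    "gameplays_between", "prior_gameplays", "day_1", "day_2"]
                   + [f"ability_{s}" for s in NCPT_SUBTESTS])
        return SimulatedCohort(participants, sessions, gameplays, pd.DataFrame(columns=gt_cols))

    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    adhd = rng.random(n) < config.p_adhd

    ages = np.empty(n)
    lo, hi = config.age_truncation
    _truncated_ages(rng, adhd, config.age_dist["adhd"]["mean"],
                    config.age_dist["adhd"]["sd"], lo, hi, ages)
    _truncated_ages(rng, ~adhd, config.age_dist["control"]["mean"],
                    config.age_dist["control"]["sd"], lo, hi, ages)
    ages = np.round(ages, 1)

    gender = np.empty(n, dtype=object)
    for group, mask in (("adhd", adhd), ("control", ~adhd)):
        probs = np.array([config.gender_probs[group].get(g, 0.0) for g in GENDERS])
        gender[mask] = _choice(rng, list(GENDERS), probs, int(mask.sum()))

    edu_levels = list(config.education_probs)
    education = _choice(rng, edu_levels,
                        np.array([config.education_probs[e] for e in edu_levels]), n)
    education[rng.random(n) < config.p_education_missing] = None

    survey_completed = rng.random(n) >= config.p_survey_missing

    participants = pd.DataFrame({
        "participant_id": pid, "age": ages, "gender": gender,
        "education": education, "survey_completed": survey_completed,
    })
    # condition checklist flags; participants without a completed survey carry
    # no information (all False) and are excluded downstream
    participants["adhd"] = adhd & survey_completed
    for cond in all_conditions:
        if cond == "adhd":
            continue
        spec = config.comorbidity_log_odds.get(cond)
        if spec is None:
            flags = np.zeros(n, dtype=bool)
        else:
            p = expit(spec["intercept"] + spec["adhd_coef"] * adhd.astype(float))
            flags = rng.random(n) < p
        participants[cond] = flags & survey_completed

    # ---- assessment schedule and gameplay dose ---------------------------
    day1 = rng.integers(15, 120, n)   # leaves room for pre-baseline gameplay days
    gap = config.interval_min_days + np.round(
        rng.exponential(config.interval_mean_extra_days, n)).astype(int)
    day2 = day1 + gap

    heavy = rng.random(n) < config.p_prior_heavy
    prior_low = rng.integers(0, 26, n)
    prior_high = rng.integers(26, 200, n)
    prior = np.where(heavy, prior_high, prior_low)

    strata = list(config.dose_dist)
    stratum = _choice(rng, strata, np.array([config.dose_dist[s] for s in strata]), n)
    between = np.zeros(n, dtype=int)
    m = stratum == "low"
    between[m] = rng.integers(0, 26, int(m.sum()))
    for name, (blo, bhi) in (("intermediate", (26, 399)), ("high", (400, 2000))):
        m = stratum == name
        # log-uniform within the stratum: few users at the heavy end
        u = rng.uniform(np.log(blo), np.log(bhi + 1), int(m.sum()))
        between[m] = np.minimum(np.exp(u).astype(int), bhi)

    take_ncpt = rng.random(n) < config.p_take_ncpt
    second_ncpt = take_ncpt & (rng.random(n) < config.retention["ncpt"])
    take_bams = rng.random(n) < config.p_take_bams
    second_bams = take_bams & (rng.random(n) < config.retention["bams"])

    # ---- latent cognitive abilities --------------------------------------
    lam = config.general_factor_loading
    g_factor = rng.standard_normal(n)
    abilities = {}
    for sub in NCPT_SUBTESTS:
        spec = rng.standard_normal(n)
        abilities[sub] = lam * g_factor + np.sqrt(1.0 - lam**2) * spec

    log_dose = np.log1p(between)

    ncpt_rows = []
    for sess_idx, mask in ((1, take_ncpt), (2, second_ncpt)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        for sub in NCPT_SUBTESTS:
            p = config.subtest_params[sub]
            sign = -1.0 if p.direction == "lower_raw_better" else 1.0
            perf = (p.age_slope * (ages[idx] - 50.0)
                    + p.age_quad * (ages[idx] - 50.0) ** 2
                    + np.array([p.gender_offset.get(g, 0.0) for g in gender[idx]])
                    + abilities[sub][idx] * p.sd
                    - p.adhd_deficit * adhd[idx])
            if sess_idx == 2:
                perf = perf + p.noise_sd * (config.retest_gain["ncpt"]
                                            + config.dose_effect_slope["ncpt"] * log_dose[idx])
            perf = perf + rng.standard_normal(idx.size) * p.noise_sd
            raw = np.round(p.mean + sign * perf, 1)
            ncpt_rows.append(pd.DataFrame({
                "participant_id": pid[idx], "instrument": "NCPT",
                "session_index": sess_idx,
                "day": np.where(sess_idx == 1, day1[idx], day2[idx]),
                "measure": sub, "raw_score": raw, "response_label": None,
            }))

    # ---- scale items ------------------------------------------------------
    item_map = load_item_map()
    att_trait = rng.standard_normal(n)
    mood_trait = rng.standard_normal(n)
    bams_rows = []
    for sess_idx, mask in ((1, take_bams), (2, second_bams)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        for item in BAMS_ITEMS:
            p = config.bams_params[item]
            if item in ATTENTION_ITEMS:
                loading, trait = ATTENTION_ITEM_LOADING, att_trait
                slope = config.dose_effect_slope["bams_attention"]
            else:
                loading, trait = MOOD_ITEM_LOADING, mood_trait
                slope = config.dose_effect_slope["bams_mood"]
            latent = (loading * trait[idx]
                      + np.sqrt(1.0 - loading**2) * rng.standard_normal(idx.size))
            latent = p.mean + p.sd * latent - p.adhd_deficit * adhd[idx]
            if sess_idx == 2:
                latent = latent + p.sd * (config.retest_gain["bams"] + slope * log_dose[idx])
            score = np.digitize((latent - p.mean) / p.sd, _LIKERT_CUTS)
            spec = item_map.items[item]
            labels = np.array([
                spec.label_for_score(int(s)) for s in score], dtype=object)
            labels[rng.random(idx.size) < config.p_na] = "N/A"
            bams_rows.append(pd.DataFrame({
                "participant_id": pid[idx], "instrument": "BAMS7",
                "session_index": sess_idx,
                "day": np.where(sess_idx == 1, day1[idx], day2[idx]),
                "measure": item, "raw_score": np.nan, "response_label": labels,
            }))

    frames = ncpt_rows + bams_rows
    if frames:
        sessions = pd.concat(frames, ignore_index=True)
        sessions = sessions.sort_values(
            ["participant_id", "instrument", "session_index", "measure"],
            kind="mergesort").reset_index(drop=True)
    else:
        sessions = pd.DataFrame(columns=SESSION_COLUMNS)

    # ---- gameplay events --------------------------------------------------
    # prior plays land strictly before the first assessment day; intervening
    # plays are spread over four days inside (day1, day2]
    frac = rng.dirichlet(np.ones(4), size=n)
    chunks = np.floor(frac * between[:, None]).astype(int)
    remainder = between - chunks.sum(axis=1)
    chunks[:, 0] += remainder
    gp_frames = []
    prior_day = np.maximum(day1 - 14, 0)
    m = prior > 0
    gp_frames.append(pd.DataFrame({
        "participant_id": pid[m], "day": prior_day[m], "n_plays": prior[m]}))
    for j, q in enumerate((0.2, 0.4, 0.6, 0.8)):
        day_j = day1 + np.maximum(1, np.round(q * gap).astype(int))
        day_j = np.minimum(day_j, day2)
        m = chunks[:, j] > 0
        gp_frames.append(pd.DataFrame({
            "participant_id": pid[m], "day": day_j[m], "n_plays": chunks[m, j]}))
    gameplays = pd.concat(gp_frames, ignore_index=True)
    gameplays = (gameplays.groupby(["participant_id", "day"], as_index=False)["n_plays"]
                 .sum().sort_values(["participant_id", "day"]).reset_index(drop=True))

    ground_truth = pd.DataFrame({
        "participant_id": pid, "adhd_true": adhd,
        "dose_stratum_intent": stratum, "gameplays_between": between,
        "prior_gameplays": prior, "day_1": day1,
        "day_2": np.where(second_ncpt | second_bams, day2, -1),
    })
    for sub in NCPT_SUBTESTS:
        ground_truth[f"ability_{sub}"] = abilities[sub]

    return SimulatedCohort(participants, sessions, gameplays, ground_truth)


# ---------------------------------------------------------------------------
# Reference population distribution (stand-in for a census microdata sample)
# ---------------------------------------------------------------------------

def age_bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def assign_age_bins(ages, age_bins=AGE_BINS) -> pd.Series:
    """Map ages to the configured closed age bins; out-of-range ages -> NaN."""
    ages = pd.Series(np.asarray(ages, dtype=float))
    labels = pd.Series([None] * len(ages), dtype=object)
    for lo, hi in age_bins:
        m = (ages >= lo) & (ages <= hi)
        labels[m.to_numpy()] = age_bin_label(lo, hi)
    return labels


def cell_labels(age_bin: pd.Series, education: pd.Series) -> pd.Series:
    return age_bin.astype(object) + "|" + education.astype(object)


def generate_reference_distribution(config: GeneratorConfig,
                                    age_bins=AGE_BINS) -> pd.DataFrame:
    """Joint age-bin x education reference table with population proportions.

    ``matched`` mode reproduces the generator's own eligible-population
    demographics (truncated-normal age mixture x education margins), so the
    normative sample matches the reference and all weights are near 1.
    ``uniform`` gives equal mass to every cell; ``custom`` passes through the
    configured proportions after normalization.
    """
    if not age_bins:
        raise ConfigurationError("age_bins must be non-empty")
    edu_levels = [e for e in config.education_probs if config.education_probs[e] > 0]
    if not edu_levels:
        raise ConfigurationError("education_probs has no positive-probability level")

    rows = []
    if config.reference_mode == "custom":
        custom = config.reference_custom or {}
        if not custom:
            raise ConfigurationError("reference_custom is empty")
        total = float(sum(custom.values()))
        if total <= 0:
            raise ConfigurationError("reference_custom proportions must sum to > 0")
        if any(v < 0 for v in custom.values()):
            raise ConfigurationError("reference_custom proportions must be >= 0")
        for key, val in custom.items():
            bin_lab, edu = key.split("|")
            rows.append((bin_lab, edu, val / total))
    elif config.reference_mode == "uniform":
        k = len(age_bins) * len(edu_levels)
        for lo, hi in age_bins:
            for edu in edu_levels:
                rows.append((age_bin_label(lo, hi), edu, 1.0 / k))
    else:  # matched
        lo_t, hi_t = config.age_truncation
        bin_mass = np.zeros(len(age_bins))
        for group, weight in (("adhd", config.p_adhd), ("control", 1.0 - config.p_adhd)):
            mean, sd = config.age_dist[group]["mean"], config.age_dist[group]["sd"]
            a, b = (lo_t - mean) / sd, (hi_t - mean) / sd
            dist = truncnorm(a, b, loc=mean, scale=sd)
            for i, (blo, bhi) in enumerate(age_bins):
                bin_mass[i] += weight * (dist.cdf(bhi + 1e-9) - dist.cdf(blo))
        bin_mass /= bin_mass.sum()
        edu_total = sum(config.education_probs[e] for e in edu_levels)
        for (blo, bhi), mass in zip(age_bins, bin_mass):
            for edu in edu_levels:
                rows.append((age_bin_label(blo, bhi), edu,
                             mass * config.education_probs[edu] / edu_total))

    ref = pd.DataFrame(rows, columns=["age_bin", "education", "proportion"])
    ref["proportion"] = ref["proportion"] / ref["proportion"].sum()
    return ref


# ---------------------------------------------------------------------------
# Lightweight efficacy-cohort simulator (change scores on the composite scale)
# ---------------------------------------------------------------------------

def simulate_efficacy_change(n_low: int, n_high: int, std_effect: float,
                             rng: np.random.Generator, *,
                             baseline_mean: float = 100.0, baseline_sd: float = 15.0,
                             change_noise_sd: float = 8.0, retest_gain: float = 2.5,
                             age_coef: float = 0.06, age2_coef: float = -0.002,
                             gender_shift: float = 0.6) -> pd.DataFrame:
    """Two-dose efficacy cohort with change scores on the normed (mean-100)
    composite scale.

    The injected dose effect is ``std_effect`` times the residual change SD,
    added to the high-dose stratum, on top of a retest gain common to both
    strata and an age/gender covariate structure, so covariate
    residualization followed by a standardized group contrast should recover
    ``std_effect``.
    """
    n = n_low + n_high
    stratum = np.array(["low"] * n_low + ["high"] * n_high, dtype=object)
    a, b = (18 - 45.0) / 15.5, (90 - 45.0) / 15.5
    age = truncnorm.rvs(a, b, loc=45.0, scale=15.5, size=n, random_state=rng)
    gender = _choice(rng, list(GENDERS), np.array([0.42, 0.51, 0.07]), n)
    baseline = rng.normal(baseline_mean, baseline_sd, n) - 0.08 * (age - 45.0)
    covar = (age_coef * (age - 45.0) + age2_coef * (age - 45.0) ** 2
             + gender_shift * (gender == "female"))
    change = (retest_gain + covar
              + std_effect * change_noise_sd * (stratum == "high")
              + rng.normal(0.0, change_noise_sd, n))
    return pd.DataFrame({"stratum": stratum, "age": age, "gender": gender,
                         "baseline": baseline, "change": change})
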