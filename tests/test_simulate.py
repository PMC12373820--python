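"""Generator: determinism, injected structure, schedules, reference tables."""

import numpy as np
import pandas as pd
import pytest

from ctdose.config import GeneratorConfig, NCPT_SUBTESTS, SubtestParams
from ctdose.exceptions import ConfigurationError
from ctdose.simulate import (generate_cohort, generate_reference_distribution,
                             simulate_efficacy_change)


def test_empty_cohort_has_headers_only():
    cohort = generate_cohort(GeneratorConfig(n_participants=0))
    assert len(cohort.participants) == 0 and "participant_id" in cohort.participants
    assert len(cohort.sessions) == 0 and "raw_score" in cohort.sessions
    assert len(cohort.gameplays) == 0 and "n_plays" in cohort.gameplays


def test_same_seed_bit_identical():
    a = generate_cohort(GeneratorConfig(n_participants=400, seed=5))
    b = generate_cohort(GeneratorConfig(n_participants=400, seed=5))
    for x, y in ((a.participants, b.participants), (a.sessions, b.sessions),
                 (a.gameplays, b.gameplays), (a.ground_truth, b.ground_truth)):
        pd.testing.assert_frame_equal(x, y)


def test_different_seed_differs():
    a = generate_cohort(GeneratorConfig(n_participants=400, seed=5))
    b = generate_cohort(GeneratorConfig(n_participants=400, seed=6))
    assert not a.participants["age"].equals(b.participants["age"])


@pytest.mark.parametrize("field,value,fragment", [
    ("n_participants", -1, "n_participants"),
    ("p_adhd", 1.5, "p_adhd"),
    ("dose_dist", {"low": 0.5, "intermediate": 0.2, "high": 0.2}, "dose_dist"),
    ("reference_mode", "bogus", "reference_mode"),
])
def test_invalid_config_names_field(field, value, fragment):
    cfg = GeneratorConfig()
    setattr(cfg, field, value)
    with pytest.raises(ConfigurationError, match=fragment):
        cfg.validate()


def test_injected_adhd_deficit_recovered_monte_carlo():
    """A deficit of 0.5 session-noise SDs shows up as a standardized
    ADHD-control difference of 0.5 +/- 0.05 when all other variance
    sources on that subtest are switched off (n = 20,000)."""
    cfg = GeneratorConfig(n_participants=20_000, seed=42, p_take_ncpt=1.0,
                          p_take_bams=0.0)
    cfg.retention = {"ncpt": 0.0, "bams": 0.0}
    sub = "arithmetic_reasoning"
    cfg.subtest_params[sub] = SubtestParams(
        mean=20.0, sd=0.01, age_slope=0.0, age_quad=0.0, gender_offset={},
        adhd_deficit=5.0, noise_sd=10.0)
    cohort = generate_cohort(cfg)
    s1 = cohort.sessions[(cohort.sessions["measure"] == sub)
                         & (cohort.sessions["session_index"] == 1)]
    merged = s1.merge(cohort.ground_truth[["participant_id", "adhd_true"]],
                      on="participant_id")
    a = merged[merged["adhd_true"]]["raw_score"]
    c = merged[~merged["adhd_true"]]["raw_score"]
    sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(c) - 1) * c.var(ddof=1))
                 / (len(a) + len(c) - 2))
    std_diff = (c.mean() - a.mean()) / sp
    assert abs(std_diff - 0.5) < 0.05


def test_zero_gain_zero_slope_mean_change_is_zero():
    cfg = GeneratorConfig(n_participants=8000, seed=3, p_take_ncpt=1.0, p_take_bams=0.0)
    cfg.retest_gain = {"ncpt": 0.0, "bams": 0.0}
    cfg.dose_effect_slope = {"ncpt": 0.0, "bams_attention": 0.0, "bams_mood": 0.0}
    cfg.retention = {"ncpt": 1.0, "bams": 0.0}
    cohort = generate_cohort(cfg)
    for sub in NCPT_SUBTESTS:
        rows = cohort.sessions[cohort.sessions["measure"] == sub]
        wide = rows.pivot_table(index="participant_id", columns="session_index",
                                values="raw_score").dropna()
        change = wide[2] - wide[1]
        noise = cfg.subtest_params[sub].noise_sd
        # Monte-Carlo error on the mean change at n=8000
        assert abs(change.mean()) < 4 * noise * np.sqrt(2 / len(change))


def test_sessions_at_least_ten_weeks_apart_and_doses_in_range(small_cohort):
    s = small_cohort.sessions
    days = s.groupby(["participant_id", "instrument", "session_index"])["day"].first()
    wide = days.unstack("session_index")
    both = wide.dropna()
    assert ((both[2] - both[1]) >= 70).all()
    gt = small_cohort.ground_truth
    low = gt[gt["dose_stratum_intent"] == "low"]["gameplays_between"]
    high = gt[gt["dose_stratum_intent"] == "high"]["gameplays_between"]
    mid = gt[gt["dose_stratum_intent"] == "intermediate"]["gameplays_between"]
    assert len(low) and len(high)   # both contrast strata populated by default
    assert low.between(0, 25).all()
    assert mid.between(26, 399).all()
    assert high.between(400, 2000).all()


def test_prior_gameplays_precede_first_assessment(small_cohort):
    gt = small_cohort.ground_truth.set_index("participant_id")
    gp = small_cohort.gameplays.merge(gt[["day_1", "prior_gameplays"]],
                                      on="participant_id")
    before = gp[gp["day"] < gp["day_1"]].groupby("participant_id")["n_plays"].sum()
    with_prior = gt[gt["prior_gameplays"] > 0]
    assert (before.reindex(with_prior.index, fill_value=0)
            == with_prior["prior_gameplays"]).all()


def test_comorbidity_log_odds_recovered_in_coverage():
    """The injected ADHD log-odds for anxiety is inside the fitted 95% CI in
    >= 90% of 100 seeded replicates (logistic model with age + age^2 +
    gender covariates, as in the comorbidity analysis)."""
    from ctdose.stats import comorbidity_odds

    true_log_or = np.log(2.5)
    hits = 0
    for seed in range(100):
        cfg = GeneratorConfig(n_participants=2500, seed=seed,
                              p_take_ncpt=0.0, p_take_bams=0.0,
                              p_survey_missing=0.0)
        cohort = generate_cohort(cfg)
        p = cohort.participants
        est = comorbidity_odds(p["anxiety"].to_numpy(), p["adhd"].to_numpy(),
                               p["age"].to_numpy(), p["gender"].to_numpy())
        if est.ci_low <= np.exp(true_log_or) <= est.ci_high:
            hits += 1
    assert hits >= 90


def test_reference_distribution_modes():
    cfg = GeneratorConfig(reference_mode="uniform")
    ref = generate_reference_distribution(cfg)
    assert np.allclose(ref["proportion"], ref["proportion"].iloc[0])
    assert abs(ref["proportion"].sum() - 1.0) < 1e-9

    cfg = GeneratorConfig(reference_mode="matched")
    ref = generate_reference_distribution(cfg)
    assert abs(ref["proportion"].sum() - 1.0) < 1e-9

    custom = {"18-29|hs_diploma": 3.0, "30-39|bachelor": 1.0}
    cfg = GeneratorConfig(reference_mode="custom", reference_custom=custom)
    ref = generate_reference_distribution(cfg)
    props = dict(zip(ref["age_bin"] + "|" + ref["education"], ref["proportion"]))
    assert abs(props["18-29|hs_diploma"] - 0.75) < 1e-12
    assert abs(props["30-39|bachelor"] - 0.25) < 1e-12

    with pytest.raises(ConfigurationError):
        generate_reference_distribution(GeneratorConfig(), age_bins=())


def test_efficacy_change_simulator_injects_standardized_effect(rng):
    df = simulate_efficacy_change(4000, 4000, 0.5, rng)
    lo = df[df["stratum"] == "low"]["change"]
    hi = df[df["stratum"] == "high"]["change"]
    # raw contrast contains covariate noise too, so compare against the
    # injected shift in raw units
    assert abs((hi.mean() - lo.mean()) - 0.5 * 8.0) < 0.6
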