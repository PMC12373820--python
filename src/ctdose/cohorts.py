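"""Eligibility filtering, cohort assignment, and training-dose stratification.

Eligibility mirrors the study design: ages 18-90, at least one assessment,
a completed diagnosed-condition survey, no severe neuropsychological
disorder, and no more than 25 gameplays before the first assessment (to keep
baselines training-naive). Efficacy participants are stratified by gameplays
between their first two administrations of an instrument: low (<=25),
high (400-2000, inclusive), intermediate in between, above_high beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import load_condition_lists
from .exceptions import DataError

LOW_MAX = 25
HIGH_MIN = 400
HIGH_MAX = 2000

INSTRUMENTS = ("NCPT", "BAMS7")


def dose_stratum(gameplays_between: int) -> str:
    """Pure stratum assignment from an intervening-gameplay count."""
    if gameplays_between < 0:
        raise DataError(f"negative gameplay count: {gameplays_between}")
    if gameplays_between <= LOW_MAX:
        return "low"
    if gameplays_between < HIGH_MIN:
        return "intermediate"
    if gameplays_between <= HIGH_MAX:
        return "high"
    return "above_high"


def _check_linked(participants: pd.DataFrame, sessions: pd.DataFrame,
                  gameplays: pd.DataFrame) -> None:
    known = set(participants["participant_id"])
    for name, table in (("sessions", sessions), ("gameplays", gameplays)):
        if len(table) == 0:
            continue
        orphans = sorted(set(table["participant_id"]) - known)
        if orphans:
            raise DataError(f"{name} table has rows for unknown participants: {orphans[:5]}"
                            + (" ..." if len(orphans) > 5 else ""))


def first_session_day(sessions: pd.DataFrame) -> pd.Series:
    """Earliest assessment day per participant across instruments."""
    firsts = sessions[sessions["session_index"] == 1]
    return firsts.groupby("participant_id")["day"].min()


def prior_gameplay_counts(participants: pd.DataFrame, sessions: pd.DataFrame,
                          gameplays: pd.DataFrame) -> pd.Series:
    """Gameplays strictly before each participant's first assessment day."""
    first_day = first_session_day(sessions)
    gp = gameplays.merge(first_day.rename("first_day"), on="participant_id", how="inner")
    prior = (gp[gp["day"] < gp["first_day"]]
             .groupby("participant_id")["n_plays"].sum())
    return prior.reindex(participants["participant_id"], fill_value=0)


def apply_eligibility(participants: pd.DataFrame, sessions: pd.DataFrame,
                      gameplays: pd.DataFrame,
                      exclusion_conditions: list[str] | None = None,
                      age_range: tuple[float, float] = (18.0, 90.0),
                      max_prior_gameplays: int = LOW_MAX,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study eligibility filters.

    Returns (eligible participants, exclusion log). The exclusion log has one
    row per excluded participant with the first failing reason, checked in
    order: no_survey, age, excluded_condition, no_assessment, prior_gameplays.
    """
    _check_linked(participants, sessions, gameplays)
    if exclusion_conditions is None:
        _, exclusion_conditions = load_condition_lists()
    present_exclusions = [c for c in exclusion_conditions if c in participants.columns]

    df = participants.set_index("participant_id", drop=False)
    reasons = pd.Series(index=df.index, dtype=object)

    no_survey = ~df["survey_completed"].astype(bool)
    reasons[no_survey & reasons.isna()] = "no_survey"

    lo, hi = age_range
    bad_age = (df["age"] < lo) | (df["age"] > hi) | df["age"].isna()
    reasons[bad_age & reasons.isna()] = "age"

    if present_exclusions:
        excluded_cond = df[present_exclusions].astype(bool).any(axis=1)
        reasons[excluded_cond & reasons.isna()] = "excluded_condition"

    has_session = df.index.isin(sessions["participant_id"]) if len(sessions) else \
        np.zeros(len(df), dtype=bool)
    reasons[~has_session & reasons.isna()] = "no_assessment"

    with_sessions = df.index[has_session]
    prior = prior_gameplay_counts(df.loc[with_sessions], sessions, gameplays)
    too_many = prior[prior > max_prior_gameplays].index
    mask = reasons.index.isin(too_many) & reasons.isna()
    reasons[mask] = "prior_gameplays"

    excluded = reasons.dropna()
    log = pd.DataFrame({"participant_id": excluded.index, "reason": excluded.values})
    eligible = participants[~participants["participant_id"].isin(excluded.index)].copy()
    return eligible.reset_index(drop=True), log.reset_index(drop=True)


@dataclass(frozen=True)
class CohortSpec:
    """Which condition flags define the two comparison groups."""

    exclusion_conditions: tuple[str, ...]


def assign_cohorts(eligible: pd.DataFrame, sessions: pd.DataFrame,
                   condition_columns: list[str] | None = None) -> pd.DataFrame:
    """Assign Overall / Baseline / Efficacy cohort labels per participant.

    Overall splits on the ADHD flag (ADHD_plus vs ADHD_minus). Baseline
    cohorts require >=1 session of the instrument; Efficacy >=2. The
    ADHD-SRLD group is everyone with the ADHD flag (other non-excluding
    conditions allowed); Healthy Controls report no diagnosed condition at
    all, so the two groups never overlap.
    """
    if condition_columns is None:
        conditions, _ = load_condition_lists()
        condition_columns = [c for c in conditions if c in eligible.columns]
    df = eligible.set_index("participant_id", drop=False)
    adhd = df["adhd"].astype(bool)
    any_condition = df[condition_columns].astype(bool).any(axis=1)

    counts = {}
    for inst in INSTRUMENTS:
        sub = sessions[sessions["instrument"] == inst]
        counts[inst] = (sub.groupby("participant_id")["session_index"].max()
                        .reindex(df.index, fill_value=0))

    out = pd.DataFrame({
        "participant_id": df["participant_id"],
        "overall": np.where(adhd, "ADHD_plus", "ADHD_minus"),
        "group": np.where(adhd, "ADHD_SRLD",
                          np.where(~any_condition, "healthy_control", "other")),
    })
    for inst, col in (("NCPT", "ncpt"), ("BAMS7", "bams")):
        out[f"baseline_{col}"] = (counts[inst] >= 1).to_numpy()
        out[f"efficacy_{col}"] = (counts[inst] >= 2).to_numpy()
    return out.reset_index(drop=True)


def gameplays_between_sessions(sessions: pd.DataFrame, gameplays: pd.DataFrame,
                               instrument: str) -> pd.DataFrame:
    """Gameplay counts in the half-open window (first-session day, second-
    session day] for participants with >=2 sessions of ``instrument``."""
    sub = sessions[(sessions["instrument"] == instrument)
                   & sessions["session_index"].isin([1, 2])]
    days = (sub.groupby(["participant_id", "session_index"])["day"].first()
            .unstack("session_index"))
    if 1 not in days.columns or 2 not in days.columns or days[[1, 2]].dropna().empty:
        return pd.DataFrame(columns=["participant_id", "day_1", "day_2", "gameplays_between"])
    days = days[[1, 2]].dropna()
    days.columns = ["day_1", "day_2"]
    gp = gameplays.merge(days.reset_index(), on="participant_id", how="inner")
    in_window = gp[(gp["day"] > gp["day_1"]) & (gp["day"] <= gp["day_2"])]
    counts = in_window.groupby("participant_id")["n_plays"].sum()
    out = days.reset_index()
    out["gameplays_between"] = counts.reindex(out["participant_id"], fill_value=0).to_numpy()
    return out


def stratify_dose(sessions: pd.DataFrame, gameplays: pd.DataFrame,
                  instrument: str,
                  participant_ids: pd.Series | None = None) -> pd.DataFrame:
    """Dose stratum per twice-assessed participant for one instrument.

    Counts >2000 fall outside the printed high range; they are labeled
    ``above_high`` and excluded from the two-stratum contrast (they enter
    only the dose-curve sensitivity analysis).
    """
    between = gameplays_between_sessions(sessions, gameplays, instrument)
    if participant_ids is not None:
        between = between[between["participant_id"].isin(set(participant_ids))]
    if between.empty:
        raise DataError(f"no participants with >= 2 {instrument} sessions")
    between = between.copy()
    between["instrument"] = instrument
    between["stratum"] = between["gameplays_between"].map(dose_stratum)
    return between.reset_index(drop=True)
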