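"""End-to-end study pipeline.

Orchestrates: simulate (or read) tables -> eligibility and cohorts -> norm
the battery -> score the scale -> dose stratification -> baseline,
comorbidity, dose-effect, effect-size, and responder analyses -> report.
Every numeric report cell traces to one EffectEstimate / ResponderResult row
in the tidy effects tables, and runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .bams import load_item_map, score_sessions
from .cohorts import (apply_eligibility, assign_cohorts, stratify_dose)
from .config import ATTENTION_ITEMS, MOOD_ITEMS, NCPT_SUBTESTS, GeneratorConfig
from .exceptions import ConfigurationError, DataError, NumericalError
from .norming import GI_MEASURE_ID, NcptNormScaler, poststratification_weights
from .simulate import (SimulatedCohort, assign_age_bins, cell_labels,
                       generate_cohort, generate_reference_distribution)
from .stats import (EffectEstimate, ResponderResult, bonferroni, comorbidity_odds,
                    gender_chisq, hedges_g, residualize, responder_threshold,
                    response_odds, welch_t)

COMORBID_CONDITIONS = ("anxiety", "depression", "substance_use_disorder", "sleep_disorder")

NCPT_MEASURES = (GI_MEASURE_ID,) + NCPT_SUBTESTS
BAMS_MEASURES = ("attention", "mood") + ATTENTION_ITEMS + MOOD_ITEMS
AGGREGATES = {GI_MEASURE_ID, "attention", "mood"}


def _family_of(measure: str) -> tuple[str | None, int]:
    """Bonferroni family label and size for a measure (aggregates unadjusted)."""
    if measure in AGGREGATES:
        return None, 1
    if measure in NCPT_SUBTESTS:
        return "ncpt_subtests", len(NCPT_SUBTESTS)
    if measure in ATTENTION_ITEMS:
        return "attention_items", len(ATTENTION_ITEMS)
    if measure in MOOD_ITEMS:
        return "mood_items", len(MOOD_ITEMS)
    return None, 1


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    mode: str = "synthetic"                       # synthetic | files
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    paths: dict[str, str] = field(default_factory=dict)   # files mode: participants,
    # sessions, gameplays (+ optional reference)
    analyses: dict[str, bool] = field(default_factory=lambda: {
        "baseline": True, "comorbidity": True, "efficacy": True, "responder": True,
        "sensitivity_dose_curve": False, "sensitivity_baseline_adjust": False,
    })
    bams_policy: str = "all"
    min_distinct_norm: int = 50
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            required = {"participants", "sessions", "gameplays"}
            missing = required - set(self.paths)
            if missing:
                raise ConfigurationError(f"files mode requires paths for: {sorted(missing)}")
        else:
            self.generator.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return {"mode": self.mode, "generator": self.generator.to_dict(),
                "paths": dict(self.paths), "analyses": dict(self.analyses),
                "bams_policy": self.bams_policy,
                "min_distinct_norm": self.min_distinct_norm, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        d.pop("output_dir", None)
        base = cls()
        for k in ("analyses", "paths"):
            if k in d:
                merged = dict(getattr(base, k))
                merged.update(d[k])
                d[k] = merged
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyReport:
    """All result sections plus provenance; serializes deterministically."""

    report: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=1, allow_nan=True,
                          default=_json_default)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(self.to_json())
        for name, table in self.tables.items():
            table.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _load_tables(config: RunConfig) -> SimulatedCohort | tuple:
    if config.mode == "synthetic":
        gen = GeneratorConfig.from_dict(config.generator.to_dict())
        gen.seed = config.seed
        cohort = generate_cohort(gen)
        reference = generate_reference_distribution(gen)
        return cohort.participants, cohort.sessions, cohort.gameplays, reference, gen
    participants = pd.read_csv(config.paths["participants"])
    sessions = pd.read_csv(config.paths["sessions"])
    gameplays = pd.read_csv(config.paths["gameplays"])
    reference = (pd.read_csv(config.paths["reference"])
                 if "reference" in config.paths else None)
    if "survey_completed" not in participants.columns:
        participants["survey_completed"] = True
    return participants, sessions, gameplays, reference, None


def normative_sample(participants: pd.DataFrame, sessions: pd.DataFrame,
                     gameplays: pd.DataFrame) -> pd.DataFrame:
    """First-battery sessions eligible for norm-table construction: the full
    battery completed, <= 25 prior gameplays, age and education reported,
    age within 18-90. Returns a wide table of raw subtest scores + cells."""
    from .cohorts import prior_gameplay_counts

    first = sessions[(sessions["instrument"] == "NCPT") & (sessions["session_index"] == 1)]
    wide = first.pivot_table(index="participant_id", columns="measure",
                             values="raw_score", aggfunc="first")
    have_all = wide.notna().all(axis=1) & (wide.shape[1] >= len(NCPT_SUBTESTS))
    wide = wide[have_all]
    meta = participants.set_index("participant_id")
    wide = wide.join(meta[["age", "education"]], how="inner")
    wide = wide[wide["age"].between(18, 90) & wide["education"].notna()]
    prior = prior_gameplay_counts(
        participants[participants["participant_id"].isin(wide.index)].copy(),
        sessions, gameplays)
    wide = wide[prior.reindex(wide.index, fill_value=0) <= 25]
    wide["age_bin"] = assign_age_bins(wide["age"]).to_numpy()
    return wide.dropna(subset=["age_bin"])


def fit_norms(norm_sample: pd.DataFrame, reference: pd.DataFrame | None,
              min_distinct: int = 50) -> NcptNormScaler:
    """Fit reweighted norm tables (unit weights when no reference given)."""
    subtest_cols = [c for c in NCPT_SUBTESTS if c in norm_sample.columns]
    directions = {"trail_making_a": "lower_raw_better",
                  "trail_making_b": "lower_raw_better"}
    weights = None
    if reference is not None:
        cells = cell_labels(norm_sample["age_bin"], norm_sample["education"])
        ref_cells = set(reference["age_bin"].astype(str) + "|" + reference["education"].astype(str))
        usable = cells.isin(ref_cells)
        if not usable.all():
            # cells absent from the reference carry no reference mass
            missing = sorted(set(cells[~usable]))
            raise DataError(f"normative-sample cells missing from reference: {missing}")
        weights = poststratification_weights(cells.to_numpy(), reference)
    scaler = NcptNormScaler(directions=directions, min_distinct=min_distinct)
    scaler.fit(norm_sample[subtest_cols], sample_weight=weights)
    return scaler


def scaled_ncpt_sessions(sessions: pd.DataFrame, scaler: NcptNormScaler) -> pd.DataFrame:
    """Scale every complete battery session; one row per (participant, session)."""
    ncpt = sessions[sessions["instrument"] == "NCPT"]
    wide = ncpt.pivot_table(index=["participant_id", "session_index", "day"],
                            columns="measure", values="raw_score", aggfunc="first")
    wide = wide[wide.notna().all(axis=1)]
    scaled = scaler.transform(wide[list(scaler.columns_)])
    scaled = scaled.reset_index()
    return scaled


def _change_table(per_session: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Second-minus-first change per participant for the given measure columns."""
    s1 = per_session[per_session["session_index"] == 1].set_index("participant_id")
    s2 = per_session[per_session["session_index"] == 2].set_index("participant_id")
    common = s1.index.intersection(s2.index)
    out = pd.DataFrame(index=common)
    for m in measures:
        out[f"baseline_{m}"] = s1.loc[common, m]
        out[f"change_{m}"] = s2.loc[common, m] - s1.loc[common, m]
    return out.reset_index().rename(columns={"index": "participant_id"})


def _mean_ci(x: np.ndarray, ci: float = 0.95) -> tuple[float, float, float]:
    n = len(x)
    m = float(np.mean(x))
    if n < 2:
        return m, float("nan"), float("nan")
    half = sps.t.ppf(0.5 + ci / 2.0, n - 1) * np.std(x, ddof=1) / np.sqrt(n)
    return m, m - float(half), m + float(half)


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def _cohort_summary(eligible: pd.DataFrame, cohorts: pd.DataFrame) -> dict[str, Any]:
    merged = eligible.merge(cohorts, on="participant_id")

    def describe(sub: pd.DataFrame) -> dict[str, Any]:
        genders = sub["gender"].value_counts()
        return {"n": int(len(sub)),
                "n_male": int(genders.get("male", 0)),
                "n_female": int(genders.get("female", 0)),
                "n_not_reported": int(genders.get("not_reported", 0)),
                "mean_age": float(sub["age"].mean()) if len(sub) else float("nan"),
                "sd_age": float(sub["age"].std(ddof=1)) if len(sub) > 1 else float("nan")}

    out = {"overall": {"ADHD_plus": describe(merged[merged["overall"] == "ADHD_plus"]),
                       "ADHD_minus": describe(merged[merged["overall"] == "ADHD_minus"]),
                       "total": describe(merged)},
           "baseline": {}, "efficacy": {}}
    for group, label in (("ADHD_SRLD", "ADHD_SRLD"), ("healthy_control", "healthy_controls")):
        gsub = merged[merged["group"] == group]
        out["baseline"][label] = {
            "ncpt": describe(gsub[gsub["baseline_ncpt"]]),
            "bams": describe(gsub[gsub["baseline_bams"]])}
    adhd = merged[merged["group"] == "ADHD_SRLD"]
    out["efficacy"]["ADHD_SRLD"] = {
        "ncpt": describe(adhd[adhd["efficacy_ncpt"]]),
        "bams": describe(adhd[adhd["efficacy_bams"]])}
    return out


def _comorbidity_analysis(eligible: pd.DataFrame,
                          ) -> tuple[list[EffectEstimate], list[str]]:
    results, warnings = [], []
    for cond in COMORBID_CONDITIONS:
        if cond not in eligible.columns:
            continue
        try:
            est = comorbidity_odds(eligible[cond].to_numpy(), eligible["adhd"].to_numpy(),
                                   eligible["age"].to_numpy(), eligible["gender"].to_numpy())
        except NumericalError as exc:
            warnings.append(f"comorbidity/{cond}: {exc}")
            continue
        est.measure_id = cond
        est.p_adjusted = float(bonferroni(est.p_raw, 1))
        results.append(est)
    return results, warnings


def _baseline_deficits(per_session: pd.DataFrame, measures: list[str],
                       eligible: pd.DataFrame, cohorts: pd.DataFrame,
                       contrast_label: str) -> list[EffectEstimate]:
    """ADHD-SRLD vs healthy-control baseline contrasts, covariate-adjusted.

    Baselines are residualized on age + age^2 + gender (fit on both cohorts
    pooled); the contrast is the adjusted mean difference with a Welch test
    and Hedges g on the residuals.
    """
    base = per_session[per_session["session_index"] == 1].merge(
        eligible[["participant_id", "age", "gender"]], on="participant_id").merge(
        cohorts[["participant_id", "group"]], on="participant_id")
    base = base[base["group"].isin(["ADHD_SRLD", "healthy_control"])]
    results = []
    for m in measures:
        sub = base.dropna(subset=[m])
        resid, model = residualize(sub[m].to_numpy(), sub["age"].to_numpy(),
                                   sub["gender"].to_numpy(),
                                   fit_population=f"baseline_{contrast_label}")
        is_adhd = (sub["group"] == "ADHD_SRLD").to_numpy()
        ra, rc = resid[is_adhd], resid[~is_adhd]
        t, df, p = welch_t(ra, rc)
        g, (glo, ghi) = hedges_g(ra, rc)
        family, fsize = _family_of(m)
        se = float(np.sqrt(ra.var(ddof=1) / len(ra) + rc.var(ddof=1) / len(rc)))
        tq = sps.t.ppf(0.975, df)
        diff = float(ra.mean() - rc.mean())
        results.append(EffectEstimate(
            measure_id=m, contrast=f"baseline_adhd_vs_control_{contrast_label}",
            estimate=diff, ci_low=diff - tq * se, ci_high=diff + tq * se,
            statistic=t, statistic_type="t", df=df, p_raw=p,
            p_adjusted=float(bonferroni(p, fsize)), family=family,
            n_per_group={"ADHD_SRLD": int(is_adhd.sum()),
                         "healthy_control": int((~is_adhd).sum())}))
        results.append(EffectEstimate(
            measure_id=m, contrast=f"baseline_g_{contrast_label}",
            estimate=g, ci_low=glo, ci_high=ghi, statistic=t, statistic_type="t",
            df=df, p_raw=p, p_adjusted=float(bonferroni(p, fsize)), family=family,
            n_per_group={"ADHD_SRLD": int(is_adhd.sum()),
                         "healthy_control": int((~is_adhd).sum())}))
    return results


def _dose_group_summary(change: pd.DataFrame, aggregate_measures: list[str]) -> dict[str, Any]:
    """Dose-group comparison table: gameplay, demographics, and baselines."""
    out: dict[str, Any] = {}
    lo = change[change["stratum"] == "low"]
    hi = change[change["stratum"] == "high"]
    out["n"] = {"low": int(len(lo)), "high": int(len(hi))}
    out["gameplays"] = {s: {"mean": float(sub["gameplays_between"].mean()),
                            "min": int(sub["gameplays_between"].min()),
                            "max": int(sub["gameplays_between"].max())}
                        for s, sub in (("low", lo), ("high", hi)) if len(sub)}
    if len(lo) >= 2 and len(hi) >= 2:
        t, df, p = welch_t(lo["age"], hi["age"])
        out["age"] = {"low": {"mean": float(lo["age"].mean()), "sd": float(lo["age"].std(ddof=1))},
                      "high": {"mean": float(hi["age"].mean()), "sd": float(hi["age"].std(ddof=1))},
                      "welch_p": p}
        chi2, dof, p_gender = gender_chisq(lo["gender"], hi["gender"])
        out["gender"] = {
            "low": lo["gender"].value_counts(normalize=True).round(4).to_dict(),
            "high": hi["gender"].value_counts(normalize=True).round(4).to_dict(),
            "chi2_p": p_gender}
        out["baseline"] = {}
        for m in aggregate_measures:
            col = f"baseline_{m}"
            sub = change.dropna(subset=[col])
            slo, shi = sub[sub["stratum"] == "low"], sub[sub["stratum"] == "high"]
            if len(slo) < 2 or len(shi) < 2:
                continue
            _, _, p_raw_base = welch_t(slo[col], shi[col])
            entry = {
                "low_raw": {"mean": float(slo[col].mean()), "sd": float(slo[col].std(ddof=1))},
                "high_raw": {"mean": float(shi[col].mean()), "sd": float(shi[col].std(ddof=1))},
                "welch_p_raw": p_raw_base}
            try:
                resid, _ = residualize(sub[col].to_numpy(), sub["age"].to_numpy(),
                                       sub["gender"].to_numpy(), fit_population="dose_groups")
            except NumericalError:
                resid = None   # cohort too small for the covariate fit
            if resid is not None:
                adj = resid + float(sub[col].mean())
                adj_lo = adj[(sub["stratum"] == "low").to_numpy()]
                adj_hi = adj[(sub["stratum"] == "high").to_numpy()]
                _, _, p_adj = welch_t(adj_lo, adj_hi)
                entry.update({
                    "low_adjusted": {"mean": float(adj_lo.mean()),
                                     "sd": float(adj_lo.std(ddof=1))},
                    "high_adjusted": {"mean": float(adj_hi.mean()),
                                      "sd": float(adj_hi.std(ddof=1))},
                    "welch_p_adjusted": p_adj})
            out["baseline"][m] = entry
    return out


def _efficacy_analyses(change_all: pd.DataFrame, change_adhd: pd.DataFrame,
                       measures: list[str], instrument: str,
                       baseline_adjust: bool = False,
                       strata: tuple[str, ...] = ("low", "high"),
                       ) -> tuple[list[EffectEstimate], dict[str, Any]]:
    """Dose effects in points and effect sizes on residualized change scores.

    The covariate model is fitted on ALL twice-tested participants
    (``change_all``); residuals are extracted for the ADHD-SRLD subset.
    """
    effects: list[EffectEstimate] = []
    points: dict[str, Any] = {}
    for m in measures:
        col = f"change_{m}"
        fit = change_all.dropna(subset=[col])
        covars = [fit["age"].to_numpy(), fit["gender"].to_numpy()]
        outcome = fit[col].to_numpy()
        if baseline_adjust:
            # sensitivity: add the baseline score to the covariate fit
            resid0, model = residualize(outcome, covars[0], covars[1],
                                        fit_population=f"twice_tested_{instrument}")
            bas = fit[f"baseline_{m}"].to_numpy()
            bas_c = bas - bas.mean()
            slope = float(np.dot(bas_c, resid0) / np.dot(bas_c, bas_c))
            resid_fit = resid0 - slope * bas_c
            resid = pd.Series(resid_fit, index=fit["participant_id"])
        else:
            resid_vals, model = residualize(outcome, covars[0], covars[1],
                                            fit_population=f"twice_tested_{instrument}")
            resid = pd.Series(resid_vals, index=fit["participant_id"])
        sub = change_adhd.dropna(subset=[col])
        sub = sub[sub["stratum"].isin(strata)]
        resid_sub = resid.reindex(sub["participant_id"])
        sub = sub.assign(resid=resid_sub.to_numpy())
        lo = sub[sub["stratum"] == "low"]
        hi = sub[sub["stratum"] == "high"]
        if len(lo) < 2 or len(hi) < 2:
            continue
        family, fsize = _family_of(m)
        t, df, p = welch_t(hi["resid"], lo["resid"])
        se = float(np.sqrt(hi["resid"].var(ddof=1) / len(hi)
                           + lo["resid"].var(ddof=1) / len(lo)))
        tq = sps.t.ppf(0.975, df)
        diff = float(hi["resid"].mean() - lo["resid"].mean())
        n_groups = {"low": int(len(lo)), "high": int(len(hi))}
        effects.append(EffectEstimate(
            measure_id=m, contrast=f"dose_points_{instrument}",
            estimate=diff, ci_low=diff - tq * se, ci_high=diff + tq * se,
            statistic=t, statistic_type="t", df=df, p_raw=p,
            p_adjusted=float(bonferroni(p, fsize)), family=family, n_per_group=n_groups))
        g, (glo, ghi) = hedges_g(hi["resid"], lo["resid"])
        effects.append(EffectEstimate(
            measure_id=m, contrast=f"dose_g_{instrument}",
            estimate=g, ci_low=glo, ci_high=ghi, statistic=t, statistic_type="t",
            df=df, p_raw=p, p_adjusted=float(bonferroni(p, fsize)), family=family,
            n_per_group=n_groups))
        if m in AGGREGATES:
            raw_lo = _mean_ci(lo[col].to_numpy())
            raw_hi = _mean_ci(hi[col].to_numpy())
            points[m] = {"low": {"mean_change": raw_lo[0], "ci": [raw_lo[1], raw_lo[2]]},
                         "high": {"mean_change": raw_hi[0], "ci": [raw_hi[1], raw_hi[2]]}}
    return effects, points


def _responder_analysis(change_adhd: pd.DataFrame, measures: list[str],
                        instrument: str) -> list[ResponderResult]:
    """Half-SD responder classification; thresholds from the baseline scores
    of the entire twice-tested ADHD-SRLD cohort (all dose strata pooled)."""
    results = []
    for m in measures:
        col, bcol = f"change_{m}", f"baseline_{m}"
        pooled = change_adhd.dropna(subset=[bcol])
        if len(pooled) < 2:
            continue
        thr = responder_threshold(pooled[bcol].to_numpy())
        sub = change_adhd.dropna(subset=[col])
        lo = sub[sub["stratum"] == "low"][col].to_numpy()
        hi = sub[sub["stratum"] == "high"][col].to_numpy()
        if len(lo) == 0 or len(hi) == 0:
            continue
        res = response_odds(lo, hi, thr, measure_id=f"{m}")
        results.append(res)
    return results


def _sensitivity_dose_curve(change_all: pd.DataFrame, change_adhd: pd.DataFrame,
                            measures: list[str], instrument: str) -> dict[str, Any]:
    """Per-stratum effects including intermediate doses (low as reference)."""
    out: dict[str, Any] = {}
    warnings: list[str] = []
    for m in measures:
        if m not in AGGREGATES:
            continue
        col = f"change_{m}"
        fit = change_all.dropna(subset=[col])
        resid_vals, _ = residualize(fit[col].to_numpy(), fit["age"].to_numpy(),
                                    fit["gender"].to_numpy(),
                                    fit_population=f"twice_tested_{instrument}")
        resid = pd.Series(resid_vals, index=fit["participant_id"])
        sub = change_adhd.dropna(subset=[col]).copy()
        sub["resid"] = resid.reindex(sub["participant_id"]).to_numpy()
        lo = sub[sub["stratum"] == "low"]["resid"].to_numpy()
        entry: dict[str, Any] = {}
        for stratum in ("low", "intermediate", "high"):
            grp = sub[sub["stratum"] == stratum]["resid"].to_numpy()
            if len(grp) < 2:
                warnings.append(f"{instrument}/{m}: stratum {stratum!r} too small; skipped")
                continue
            mean, clo, chi_ = _mean_ci(grp)
            cell = {"n": int(len(grp)), "mean_resid_change": mean, "ci": [clo, chi_]}
            if stratum != "low" and len(lo) >= 2:
                g, (glo, ghi) = hedges_g(grp, lo)
                cell["g_vs_low"] = {"estimate": g, "ci": [glo, ghi]}
            entry[stratum] = cell
        out[m] = entry
    if warnings:
        out["warnings"] = warnings
    return out


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_study(config: RunConfig) -> StudyReport:
    config.validate()
    participants, sessions, gameplays, reference, gen = _load_tables(config)

    eligible, exclusion_log = apply_eligibility(participants, sessions, gameplays)
    cohorts = assign_cohorts(eligible, sessions)
    eligible_sessions = sessions[sessions["participant_id"].isin(
        set(eligible["participant_id"]))]

    tables: dict[str, pd.DataFrame] = {
        "participants_eligible": eligible, "exclusion_log": exclusion_log,
        "cohort_assignments": cohorts,
    }
    report: dict[str, Any] = {}
    toggles = config.analyses
    effects_rows: list[EffectEstimate] = []
    responder_rows: list[ResponderResult] = []

    # ---- norming + scoring ----------------------------------------------
    norm_sample = normative_sample(participants, sessions, gameplays)
    scaler = fit_norms(norm_sample, reference, config.min_distinct_norm)
    scaled_ncpt = scaled_ncpt_sessions(eligible_sessions, scaler)
    tables["ncpt_scaled"] = scaled_ncpt

    bams_sessions = eligible_sessions[eligible_sessions["instrument"] == "BAMS7"]
    bams_scores = (score_sessions(bams_sessions, policy=config.bams_policy)
                   if len(bams_sessions) else pd.DataFrame(
                       columns=["participant_id", "session_index", "day"]))
    tables["bams_scores"] = bams_scores

    report["cohort_summary"] = _cohort_summary(eligible, cohorts)

    if toggles.get("comorbidity", True):
        surveyed = eligible[eligible["survey_completed"]]
        comorbid, comorbid_warnings = _comorbidity_analysis(surveyed)
        effects_rows += comorbid
        report["comorbidity_odds"] = {e.measure_id: e.to_dict() for e in comorbid}
        if comorbid_warnings:
            report.setdefault("warnings", []).extend(comorbid_warnings)

    ncpt_measures = [m for m in NCPT_MEASURES if m in scaled_ncpt.columns]
    bams_measures = [m for m in BAMS_MEASURES if m in bams_scores.columns]

    if toggles.get("baseline", True):
        baseline_effects = []
        if len(scaled_ncpt):
            baseline_effects += _baseline_deficits(scaled_ncpt, ncpt_measures,
                                                   eligible, cohorts, "ncpt")
        if len(bams_scores):
            baseline_effects += _baseline_deficits(bams_scores, bams_measures,
                                                   eligible, cohorts, "bams")
        effects_rows += baseline_effects
        report["baseline_deficits"] = [e.to_dict() for e in baseline_effects]

    # ---- efficacy stages --------------------------------------------------
    need_change = toggles.get("efficacy", True) or toggles.get("responder", True) \
        or toggles.get("sensitivity_dose_curve", False)
    if need_change:
        adhd_ids = set(cohorts[cohorts["group"] == "ADHD_SRLD"]["participant_id"])
        dose_points: dict[str, Any] = {}
        sensitivity: dict[str, Any] = {}
        for instrument, per_session, measures in (
                ("ncpt", scaled_ncpt, ncpt_measures),
                ("bams", bams_scores, bams_measures)):
            if not len(per_session) or not measures:
                continue
            change = _change_table(per_session, measures)
            if not len(change):
                continue
            inst_name = "NCPT" if instrument == "ncpt" else "BAMS7"
            try:
                strata = stratify_dose(eligible_sessions, gameplays, inst_name,
                                       participant_ids=change["participant_id"])
            except DataError:
                continue
            change = change.merge(
                strata[["participant_id", "gameplays_between", "stratum"]],
                on="participant_id", how="inner")
            change = change.merge(eligible[["participant_id", "age", "gender"]],
                                  on="participant_id")
            change_adhd = change[change["participant_id"].isin(adhd_ids)]
            tables[f"change_{instrument}"] = change
            two_lo = change_adhd[change_adhd["stratum"] == "low"]
            two_hi = change_adhd[change_adhd["stratum"] == "high"]
            if toggles.get("efficacy", True) and len(two_lo) >= 2 and len(two_hi) >= 2:
                report.setdefault("dose_group_summary", {})[instrument] = \
                    _dose_group_summary(change_adhd,
                                        [m for m in measures if m in AGGREGATES])
                eff, points = _efficacy_analyses(
                    change, change_adhd, measures, instrument,
                    baseline_adjust=toggles.get("sensitivity_baseline_adjust", False))
                effects_rows += eff
                dose_points[instrument] = points
                report.setdefault("dose_effects_points", {})[instrument] = [
                    e.to_dict() for e in eff if e.contrast.startswith("dose_points")]
                report.setdefault("dose_effect_sizes", {})[instrument] = [
                    e.to_dict() for e in eff if e.contrast.startswith("dose_g")]
            if toggles.get("responder", True) and len(two_lo) and len(two_hi):
                rr = _responder_analysis(change_adhd, measures, instrument)
                responder_rows += rr
                report.setdefault("responder_odds", {})[instrument] = [
                    r.to_dict() for r in rr]
            if toggles.get("sensitivity_dose_curve", False):
                sensitivity[instrument] = _sensitivity_dose_curve(
                    change, change_adhd, measures, instrument)
        if dose_points:
            report["change_by_dose"] = dose_points
        if sensitivity:
            report["sensitivity_dose_curve"] = sensitivity

    # ---- tidy outputs + provenance ---------------------------------------
    if effects_rows:
        tables["effects"] = pd.DataFrame([e.to_dict() for e in effects_rows])
    if responder_rows:
        tables["responders"] = pd.DataFrame([r.to_dict() for r in responder_rows])

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    report["provenance"] = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed, "package_version": __version__,
        "n_participants_input": int(len(participants)),
        "n_eligible": int(len(eligible)),
    }

    study = StudyReport(report=report, tables=tables)
    if config.output_dir:
        study.write(config.output_dir)
    return study
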