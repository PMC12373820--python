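"""Configuration objects for the synthetic cohort generator and pipeline runs.

``GeneratorConfig`` holds every parameter of the generative model: cohort
composition (ADHD prevalence, age and gender structure per group), the
comorbidity model (per-condition logistic intercept + ADHD log-odds),
per-subtest raw-score models for the 8-subtest neurocognitive battery,
per-item latent models for the 7-item attention/mood scale, retest (practice)
gains, the training dose-response slope, and the gameplay dose mixture.

All configs round-trip through plain dicts (and therefore YAML/JSON).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

from .exceptions import ConfigurationError

# Canonical measure identifiers -------------------------------------------------

NCPT_SUBTESTS = (
    "arithmetic_reasoning",
    "digit_symbol_coding",
    "forward_visual_memory_span",
    "reverse_visual_memory_span",
    "trail_making_a",
    "trail_making_b",
    "grammatical_reasoning",
    "progressive_matrices",
)

ATTENTION_ITEMS = ("lost_details", "misplaced_items", "lost_concentration", "good_concentration")
MOOD_ITEMS = ("anxious", "bad_mood", "sad")
BAMS_ITEMS = ATTENTION_ITEMS + MOOD_ITEMS

GENDERS = ("male", "female", "not_reported")

EDUCATION_LEVELS = ("less_than_hs", "hs_diploma", "some_college", "bachelor", "graduate")

AGE_BINS = ((18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 90))


def load_condition_lists() -> tuple[list[str], list[str]]:
    """Default 32-condition checklist and the severe-disorder exclusion sublist."""
    text = resources.files("ctdose.data").joinpath("conditions.yaml").read_text()
    raw = yaml.safe_load(text)
    return list(raw["conditions"]), list(raw["exclusion_conditions"])


@dataclass
class SubtestParams:
    """Generative model for one battery subtest's raw score.

    raw = mean + sign * (age terms + gender offset + ability - ADHD deficit
                         + retest/dose gains + session noise)

    where ``sign`` is -1 for completion-time subtests (lower raw is better),
    so every performance term acts in the "better performance" direction and
    the raw scale keeps its natural orientation.
    """

    mean: float
    sd: float                      # between-person (stable ability) SD, raw units
    age_slope: float = 0.0         # raw units per year past age 50 (performance direction)
    age_quad: float = 0.0          # raw units per (year past 50)^2
    gender_offset: dict[str, float] = field(default_factory=dict)  # male is reference
    adhd_deficit: float = 0.0      # raw units, performance direction
    noise_sd: float = 1.0          # within-person session noise, raw units
    direction: str = "higher_raw_better"


@dataclass
class BamsItemParams:
    """Latent-normal model for one scale item (standard-normal under the null)."""

    mean: float = 0.0
    sd: float = 1.0
    adhd_deficit: float = 0.0      # latent SD units, toward the negative pole


def _default_subtest_params() -> dict[str, SubtestParams]:
    # Raw scales mimic the underlying instruments: counts correct, symbol
    # throughput, memory spans, completion seconds for the two trail-making
    # forms (lower better), and item counts for reasoning/matrices.
    def p(mean, sd, noise, deficit, direction="higher_raw_better"):
        return SubtestParams(
            mean=mean, sd=sd,
            age_slope=-0.02 * sd, age_quad=-0.0004 * sd,
            gender_offset={"female": 0.0, "not_reported": -0.05 * sd},
            adhd_deficit=deficit, noise_sd=noise, direction=direction,
        )

    return {
        "arithmetic_reasoning": p(20.0, 6.0, 4.0, 1.2),
        "digit_symbol_coding": p(42.0, 10.0, 6.5, 2.0),
        "forward_visual_memory_span": p(6.5, 1.3, 0.9, 0.26),
        "reverse_visual_memory_span": p(6.0, 1.4, 1.0, 0.28),
        "trail_making_a": p(35.0, 11.0, 7.5, 2.2, "lower_raw_better"),
        "trail_making_b": p(75.0, 24.0, 16.0, 4.8, "lower_raw_better"),
        "grammatical_reasoning": p(15.0, 5.0, 3.5, 1.0),
        "progressive_matrices": p(8.0, 3.0, 2.1, 0.6),
    }


def _default_bams_params() -> dict[str, BamsItemParams]:
    # Baseline deficits concentrate on the attention items (largest published
    # standardized gap on the Attention subscale, smaller on Mood).
    out: dict[str, BamsItemParams] = {}
    for item in ATTENTION_ITEMS:
        out[item] = BamsItemParams(adhd_deficit=0.72)
    for item in MOOD_ITEMS:
        out[item] = BamsItemParams(adhd_deficit=0.35)
    return out


def _default_comorbidity_log_odds() -> dict[str, dict[str, float]]:
    conditions, exclusions = load_condition_lists()
    out: dict[str, dict[str, float]] = {}
    import math

    for cond in conditions:
        if cond == "adhd":
            continue
        if cond in ("anxiety", "depression"):
            out[cond] = {"intercept": -1.8, "adhd_coef": math.log(2.5)}
        elif cond == "substance_use_disorder":
            out[cond] = {"intercept": -3.4, "adhd_coef": math.log(2.8)}
        elif cond == "sleep_disorder":
            out[cond] = {"intercept": -2.4, "adhd_coef": math.log(1.8)}
        elif cond in exclusions:
            out[cond] = {"intercept": -4.6, "adhd_coef": 0.4}
        else:
            out[cond] = {"intercept": -3.0, "adhd_coef": 0.2}
    return out


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort's generative model."""

    n_participants: int = 2000
    p_adhd: float = 0.137
    # per-group truncated-normal age models (years); truncation bounds are wider
    # than study eligibility so out-of-range ages exist to exercise the filters
    age_dist: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "adhd": {"mean": 40.4, "sd": 15.9},
        "control": {"mean": 52.6, "sd": 16.4},
    })
    age_truncation: tuple[float, float] = (14.0, 95.0)
    gender_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "adhd": {"male": 0.475, "female": 0.445, "not_reported": 0.080},
        "control": {"male": 0.352, "female": 0.576, "not_reported": 0.072},
    })
    education_probs: dict[str, float] = field(default_factory=lambda: {
        "less_than_hs": 0.08, "hs_diploma": 0.26, "some_college": 0.30,
        "bachelor": 0.22, "graduate": 0.14,
    })
    p_education_missing: float = 0.02
    p_survey_missing: float = 0.02
    comorbidity_log_odds: dict[str, dict[str, float]] = field(
        default_factory=_default_comorbidity_log_odds)
    subtest_params: dict[str, SubtestParams] = field(default_factory=_default_subtest_params)
    bams_params: dict[str, BamsItemParams] = field(default_factory=_default_bams_params)
    general_factor_loading: float = 0.55   # shared cognitive factor across subtests
    # gains in units of each measure's session-noise SD
    retest_gain: dict[str, float] = field(default_factory=lambda: {"ncpt": 0.35, "bams": 0.0})
    # defaults sized so the implied high-vs-low standardized dose effects on
    # the composite GI (~0.44) and the Attention subscale (~0.5) match the
    # magnitudes reported for real cohorts of this kind
    dose_effect_slope: dict[str, float] = field(default_factory=lambda: {
        "ncpt": 0.05, "bams_attention": 0.06, "bams_mood": 0.0,
    })
    # mixture over intervening-gameplay strata: low 0-25, intermediate 26-399,
    # high 400-2000 (counts drawn log-uniform within the stratum)
    dose_dist: dict[str, float] = field(default_factory=lambda: {
        "low": 0.25, "intermediate": 0.45, "high": 0.30,
    })
    # prior (pre-baseline) gameplay: mostly light users; a small fraction heavy
    # (>25 plays) to exercise the eligibility filter
    p_prior_heavy: float = 0.03
    p_take_ncpt: float = 0.85
    p_take_bams: float = 0.30
    retention: dict[str, float] = field(default_factory=lambda: {"ncpt": 0.37, "bams": 0.26})
    interval_min_days: int = 70            # assessments at least 10 weeks apart
    interval_mean_extra_days: float = 50.0
    p_na: float = 0.01                     # "N/A" response probability per item
    reference_mode: str = "matched"        # matched | uniform | custom
    reference_custom: dict[str, float] | None = None   # "age_lo-age_hi|education" -> prop
    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> "GeneratorConfig":
        def check_prob(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")

        if not isinstance(self.n_participants, int) or self.n_participants < 0:
            raise ConfigurationError(
                f"n_participants must be a non-negative integer, got {self.n_participants!r}")
        check_prob("p_adhd", self.p_adhd)
        for name in ("p_education_missing", "p_survey_missing", "p_prior_heavy",
                     "p_take_ncpt", "p_take_bams", "p_na"):
            check_prob(name, getattr(self, name))
        for group, probs in self.gender_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"gender_probs[{group!r}] must sum to 1 within 1e-9 (sum={total!r})")
            for g, v in probs.items():
                if g not in GENDERS:
                    raise ConfigurationError(f"gender_probs[{group!r}] has unknown level {g!r}")
                check_prob(f"gender_probs[{group!r}][{g!r}]", v)
        for name, probs in (("education_probs", self.education_probs),
                            ("dose_dist", self.dose_dist),
                            ("retention", self.retention)):
            for k, v in probs.items():
                check_prob(f"{name}[{k!r}]", v)
        if abs(sum(self.education_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("education_probs must sum to 1 within 1e-9")
        if abs(sum(self.dose_dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("dose_dist must sum to 1 within 1e-9")
        for key in ("low", "intermediate", "high"):
            if key not in self.dose_dist:
                raise ConfigurationError(f"dose_dist missing stratum {key!r}")
        lo, hi = self.age_truncation
        if not lo < hi:
            raise ConfigurationError(f"age_truncation must be (lo, hi) with lo < hi, got {self.age_truncation!r}")
        for name, params in self.subtest_params.items():
            if params.sd <= 0 or params.noise_sd <= 0:
                raise ConfigurationError(f"subtest_params[{name!r}]: sd and noise_sd must be > 0")
            if params.direction not in ("higher_raw_better", "lower_raw_better"):
                raise ConfigurationError(f"subtest_params[{name!r}].direction invalid: {params.direction!r}")
        for name, params in self.bams_params.items():
            if params.sd <= 0:
                raise ConfigurationError(f"bams_params[{name!r}].sd must be > 0")
        if not (0.0 <= self.general_factor_loading < 1.0):
            raise ConfigurationError("general_factor_loading must be in [0, 1)")
        if self.interval_min_days < 0 or self.interval_mean_extra_days < 0:
            raise ConfigurationError("assessment interval parameters must be non-negative")
        if self.reference_mode not in ("matched", "uniform", "custom"):
            raise ConfigurationError(f"reference_mode invalid: {self.reference_mode!r}")
        if self.reference_mode == "custom" and not self.reference_custom:
            raise ConfigurationError("reference_mode='custom' requires reference_custom")
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")
        return self

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["age_truncation"] = list(self.age_truncation)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        if "age_truncation" in d:
            d["age_truncation"] = tuple(d["age_truncation"])
        if "subtest_params" in d:
            d["subtest_params"] = {
                k: v if isinstance(v, SubtestParams) else SubtestParams(**v)
                for k, v in d["subtest_params"].items()}
        if "bams_params" in d:
            d["bams_params"] = {
                k: v if isinstance(v, BamsItemParams) else BamsItemParams(**v)
                for k, v in d["bams_params"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
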