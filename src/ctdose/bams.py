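"""Scoring for the 7-item attention/mood self-report scale.

Raw Likert labels are recoded to 0-4 with 0 always the most negative option
(reverse scoring where the response set runs positive-to-negative), "N/A"
becomes missing, and the Attention subscale is the mean of its four items,
the Mood subscale the mean of its three. Internal consistency is estimated
with Cronbach's alpha and a Feldt F-interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import f as f_dist

from .exceptions import ConfigurationError, DataError, NumericalError

NA_LABEL = "N/A"
MAX_SCORE = 4


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    response_set: tuple[str, ...]   # ordered first-to-last as presented
    subscale: str                   # "Attention" | "Mood"
    reverse: bool                   # most negative option is the LAST label

    def score_for_label(self, label: str) -> float:
        """0-4 numeric recoding; NaN for 'N/A'."""
        if label == NA_LABEL:
            return float("nan")
        try:
            idx = self.response_set.index(label)
        except ValueError:
            raise DataError(
                f"unrecognized response {label!r} for item {self.item_id!r}; "
                f"expected one of {list(self.response_set)} or {NA_LABEL!r}") from None
        return float(MAX_SCORE - idx) if self.reverse else float(idx)

    def label_for_score(self, score: int) -> str:
        if not 0 <= score <= MAX_SCORE:
            raise ValueError(f"score must be 0..{MAX_SCORE}, got {score}")
        idx = MAX_SCORE - score if self.reverse else score
        return self.response_set[idx]


@dataclass
class ItemMap:
    items: dict[str, ItemSpec] = field(default_factory=dict)

    @property
    def subscales(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item_id, spec in self.items.items():
            out.setdefault(spec.subscale, []).append(item_id)
        return out


def load_item_map(path: str | None = None) -> ItemMap:
    """Load an item map from YAML (the packaged 7-item default if no path)."""
    if path is None:
        text = resources.files("ctdose.data").joinpath("bams7_items.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    response_sets = {k: tuple(v) for k, v in raw["response_sets"].items()}
    items: dict[str, ItemSpec] = {}
    for item_id, d in raw["items"].items():
        rs = d["response_set"]
        if rs not in response_sets:
            raise ConfigurationError(f"item {item_id!r} names unknown response_set {rs!r}")
        items[item_id] = ItemSpec(item_id=item_id, response_set=response_sets[rs],
                                  subscale=d["subscale"], reverse=bool(d["reverse"]))
    return ItemMap(items=items)


def recode_item(response_label: str, item_spec: ItemSpec) -> float:
    """Recode one Likert label to 0-4 (0 = most negative); 'N/A' -> NaN."""
    return item_spec.score_for_label(response_label)


@dataclass(frozen=True)
class BamsScores:
    attention: float
    mood: float
    n_items_used: dict[str, int]


def score_subscales(item_responses: dict[str, str], item_map: ItemMap | None = None,
                    policy: str = "all") -> BamsScores:
    """Subscale scores for one session from its 7 response labels.

    policy='all' (default) requires every item of a subscale to be non-missing;
    policy='half' requires at least half (rounded up). A subscale that fails
    its policy is NaN.
    """
    if item_map is None:
        item_map = load_item_map()
    if policy not in ("all", "half"):
        raise ConfigurationError(f"policy must be 'all' or 'half', got {policy!r}")
    missing = set(item_map.items) - set(item_responses)
    if missing:
        raise DataError(f"missing responses for items: {sorted(missing)}")

    values: dict[str, list[float]] = {}
    for item_id, spec in item_map.items.items():
        score = spec.score_for_label(item_responses[item_id])
        values.setdefault(spec.subscale, []).append(score)

    means: dict[str, float] = {}
    used: dict[str, int] = {}
    for subscale, scores in values.items():
        arr = np.asarray(scores, dtype=float)
        ok = ~np.isnan(arr)
        used[subscale] = int(ok.sum())
        needed = len(arr) if policy == "all" else int(np.ceil(len(arr) / 2))
        means[subscale] = float(arr[ok].mean()) if ok.sum() >= needed else float("nan")
    return BamsScores(attention=means.get("Attention", float("nan")),
                      mood=means.get("Mood", float("nan")), n_items_used=used)


def score_sessions(sessions: pd.DataFrame, item_map: ItemMap | None = None,
                   policy: str = "all") -> pd.DataFrame:
    """Score every scale session in a long-format table.

    Expects columns participant_id, session_index, day, measure,
    response_label (instrument rows other than the scale should be filtered
    out first). Returns one row per session with item scores and subscales.
    """
    if item_map is None:
        item_map = load_item_map()
    item_ids = list(item_map.items)
    wide = sessions.pivot_table(index=["participant_id", "session_index", "day"],
                                columns="measure", values="response_label",
                                aggfunc="first").reset_index()
    missing_cols = [i for i in item_ids if i not in wide.columns]
    if missing_cols:
        raise DataError(f"sessions table lacks items: {missing_cols}")
    out = wide[["participant_id", "session_index", "day"]].copy()
    for item_id in item_ids:
        spec = item_map.items[item_id]
        out[item_id] = wide[item_id].map(
            lambda lab: spec.score_for_label(lab) if isinstance(lab, str) else float("nan"))
    for subscale, items in item_map.subscales.items():
        block = out[items].to_numpy(dtype=float)
        needed = len(items) if policy == "all" else int(np.ceil(len(items) / 2))
        n_ok = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=1)
        mean[n_ok == 0] = np.nan
        mean[n_ok < needed] = np.nan
        out[subscale.lower()] = mean
    return out


def cronbach_alpha(item_scores, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha with a Feldt F-interval, on listwise-complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums).
    The Feldt interval uses (1 - alpha_hat)/(1 - alpha) ~ F(n-1, (n-1)(k-1)).
    """
    x = np.asarray(item_scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise NumericalError("alpha requires a 2-D matrix with >= 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise NumericalError(f"alpha requires >= 3 complete rows, got {n}")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise NumericalError("zero variance of row totals; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    q = (1.0 - ci) / 2.0
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lower = 1.0 - (1.0 - alpha) * f_dist.ppf(1.0 - q, df1, df2)
    upper = 1.0 - (1.0 - alpha) * f_dist.ppf(q, df1, df2)
    return float(alpha), (float(lower), float(upper))
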