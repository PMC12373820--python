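"""Demographically reweighted norm tables for the neurocognitive battery.

A norm table maps a subtest's raw score to a reference-population scale with
mean 100 and SD 15: each distinct raw value receives its weighted mid-rank
percentile in the normative sample (weights from post-stratification against
an age-bin x education reference distribution), which is pushed through the
inverse normal CDF. The composite Grand Index (GI) is the mean of the eight
scaled subtest scores, itself re-scaled through an analogous table built
from the normative sample's subtest means with the same weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DataError, NumericalError

SCALE_MEAN = 100.0
SCALE_SD = 15.0
SCALE_CLIP_SDS = 5.0   # scaled values clipped to mean +/- 5 SD
GI_MEASURE_ID = "GI"


def poststratification_weights(sample_cells, reference: pd.DataFrame | pd.Series) -> np.ndarray:
    """Per-observation post-stratification weights.

    weight(obs in cell c) = reference proportion of c / sample proportion of c,
    rescaled so the weights sum to the sample size. ``reference`` is either a
    Series mapping cell label -> proportion or a DataFrame with columns
    age_bin, education, proportion (cells keyed "age_bin|education").
    """
    cells = pd.Series(np.asarray(sample_cells, dtype=object))
    if len(cells) == 0:
        raise DataError("empty sample: no observations to weight")
    if cells.isna().any():
        raise DataError("sample contains observations with missing cell labels")
    if isinstance(reference, pd.DataFrame):
        ref = pd.Series(reference["proportion"].to_numpy(),
                        index=(reference["age_bin"].astype(str) + "|"
                               + reference["education"].astype(str)))
    else:
        ref = reference.astype(float)
    ref = ref / ref.sum()

    counts = cells.value_counts()
    missing = sorted(set(counts.index) - set(ref.index))
    if missing:
        raise DataError(f"sample cells missing from reference distribution: {missing}")
    n = len(cells)
    sample_prop = counts / n
    ratio = ref.reindex(counts.index) / sample_prop
    weights = cells.map(ratio).to_numpy(dtype=float)
    total = weights.sum()
    if total <= 0:
        raise NumericalError("all weights are zero: reference mass vanishes on every sample cell")
    return weights * (n / total)


@dataclass
class NormTable:
    """Serializable raw -> scaled mapping for one measure."""

    measure_id: str
    raw_values: np.ndarray          # strictly increasing knots
    scaled_values: np.ndarray       # monotone per direction
    direction: str = "higher_raw_better"
    reference_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        self.scaled_values = np.asarray(self.scaled_values, dtype=float)
        if np.any(np.diff(self.raw_values) <= 0):
            raise ConfigurationError(f"norm table {self.measure_id!r}: raw_values not strictly increasing")
        diffs = np.diff(self.scaled_values)
        ok = np.all(diffs >= 0) if self.direction == "higher_raw_better" else np.all(diffs <= 0)
        if not ok:
            raise ConfigurationError(
                f"norm table {self.measure_id!r}: scaled_values not monotone for {self.direction}")

    def to_dict(self) -> dict[str, Any]:
        return {"measure_id": self.measure_id, "direction": self.direction,
                "raw_values": self.raw_values.tolist(),
                "scaled_values": self.scaled_values.tolist(),
                "reference_meta": self.reference_meta}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NormTable":
        return cls(measure_id=d["measure_id"], raw_values=np.asarray(d["raw_values"]),
                   scaled_values=np.asarray(d["scaled_values"]),
                   direction=d.get("direction", "higher_raw_better"),
                   reference_meta=d.get("reference_meta", {}))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "NormTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_norm_table(raw_scores, weights=None, measure_id: str = "",
                     direction: str = "higher_raw_better",
                     min_distinct: int = 50,
                     reference_meta: dict[str, Any] | None = None) -> NormTable:
    """Build a norm table from a (weighted) normative sample.

    Each distinct raw value gets the weighted mid-rank percentile
    p = (cumulative weight below + half its tied weight) / total weight,
    clipped to [1/(2n), 1 - 1/(2n)], then scaled = 100 + 15 * Phi^-1(p)
    (with the percentile complemented when lower raw is better), clipped at
    +/- 5 SD. Ties share one table entry.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.ndim != 1 or len(raw) == 0:
        raise DataError(f"norm table {measure_id!r}: empty normative sample")
    if np.isnan(raw).any():
        raise DataError(f"norm table {measure_id!r}: raw scores contain NaN")
    if direction not in ("higher_raw_better", "lower_raw_better"):
        raise ConfigurationError(f"invalid direction {direction!r}")
    if weights is None:
        weights = np.ones(len(raw))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != raw.shape:
        raise DataError("weights and raw_scores must have equal length")
    if np.any(weights < 0):
        raise DataError("weights must be non-negative")

    order = np.argsort(raw, kind="mergesort")
    raw_sorted, w_sorted = raw[order], weights[order]
    uniq, start = np.unique(raw_sorted, return_index=True)
    if len(uniq) < 2:
        raise NumericalError(f"norm table {measure_id!r}: all raw values identical")
    if len(uniq) < min_distinct:
        raise DataError(
            f"norm table {measure_id!r}: {len(uniq)} distinct raw values < floor {min_distinct}")

    tied_w = np.add.reduceat(w_sorted, start)
    total = tied_w.sum()
    cum_below = np.concatenate([[0.0], np.cumsum(tied_w)[:-1]])
    p = (cum_below + 0.5 * tied_w) / total
    n = len(raw)
    p = np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    if direction == "lower_raw_better":
        p = 1.0 - p
    scaled = SCALE_MEAN + SCALE_SD * norm.ppf(p)
    scaled = np.clip(scaled, SCALE_MEAN - SCALE_CLIP_SDS * SCALE_SD,
                     SCALE_MEAN + SCALE_CLIP_SDS * SCALE_SD)
    meta = dict(reference_meta or {})
    meta.setdefault("n_observations", int(n))
    meta.setdefault("n_distinct", int(len(uniq)))
    meta.setdefault("weighted", bool(weights is not None and not np.allclose(weights, 1.0)))
    return NormTable(measure_id=measure_id, raw_values=uniq, scaled_values=scaled,
                     direction=direction, reference_meta=meta)


def scale_score(raw, norm_table: NormTable):
    """Scale raw score(s) by piecewise-linear interpolation between knots;
    raw values outside the table range are clamped to the end entries."""
    raw_arr = np.asarray(raw, dtype=float)
    if np.isnan(raw_arr).any():
        raise DataError(f"scale_score({norm_table.measure_id!r}): raw score is NaN")
    out = np.interp(raw_arr, norm_table.raw_values, norm_table.scaled_values)
    return float(out) if np.isscalar(raw) or raw_arr.ndim == 0 else out


def grand_index(scaled_subtests, gi_norm_table: NormTable):
    """Composite score: mean of the 8 scaled subtest scores, re-scaled through
    the analogous composite norm table.

    ``scaled_subtests`` is a mapping subtest -> scaled score (or a DataFrame
    of scaled columns); any missing subtest raises an error naming it.
    """
    if isinstance(scaled_subtests, pd.DataFrame):
        if scaled_subtests.isna().any().any():
            bad = scaled_subtests.columns[scaled_subtests.isna().any()].tolist()
            raise DataError(f"missing scaled subtest scores in: {bad}")
        return scale_score(scaled_subtests.mean(axis=1).to_numpy(), gi_norm_table)
    missing = [k for k, v in scaled_subtests.items() if v is None or np.isnan(v)]
    if missing:
        raise DataError(f"missing scaled subtest score for: {missing}")
    return scale_score(float(np.mean(list(scaled_subtests.values()))), gi_norm_table)


class NcptNormScaler(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: fit norm tables on a normative sample of raw
    subtest scores, then transform raw scores to the mean-100/SD-15 scale and
    append the composite GI column.

    Parameters
    ----------
    directions : mapping subtest -> 'higher_raw_better' | 'lower_raw_better'
        Defaults to higher-is-better for every column.
    min_distinct : int
        Minimum number of distinct raw values required per table.

    Fitted attributes
    -----------------
    tables_ : dict of per-subtest NormTable
    gi_table_ : NormTable for the composite
    columns_ : the subtest column order seen in fit
    """

    def __init__(self, directions: dict[str, str] | None = None, min_distinct: int = 50):
        self.directions = directions
        self.min_distinct = min_distinct

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None):
        X = pd.DataFrame(X)
        if X.shape[1] == 0 or len(X) == 0:
            raise DataError("normative sample is empty")
        directions = self.directions or {}
        self.columns_ = list(X.columns)
        self.tables_ = {}
        scaled = {}
        for col in self.columns_:
            direction = directions.get(col, "higher_raw_better")
            table = build_norm_table(X[col].to_numpy(dtype=float), sample_weight,
                                     measure_id=str(col), direction=direction,
                                     min_distinct=self.min_distinct)
            self.tables_[col] = table
            scaled[col] = scale_score(X[col].to_numpy(dtype=float), table)
        composite = np.column_stack([scaled[c] for c in self.columns_]).mean(axis=1)
        self.gi_table_ = build_norm_table(composite, sample_weight,
                                          measure_id=GI_MEASURE_ID,
                                          min_distinct=self.min_distinct)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "tables_"):
            raise NumericalError("NcptNormScaler is not fitted")
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise DataError(f"transform input lacks subtest columns: {missing}")
        out = pd.DataFrame(index=X.index)
        for col in self.columns_:
            out[col] = scale_score(X[col].to_numpy(dtype=float), self.tables_[col])
        out[GI_MEASURE_ID] = scale_score(
            out[self.columns_].mean(axis=1).to_numpy(), self.gi_table_)
        return out

    def save(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, table in {**self.tables_, GI_MEASURE_ID: self.gi_table_}.items():
            table.to_json(os.path.join(outdir, f"norm_{name}.json"))
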