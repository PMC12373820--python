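"""Norm tables: post-stratification weights, inverse-normal scaling, GI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ctdose.exceptions import DataError, NumericalError
from ctdose.norming import (NcptNormScaler, NormTable, build_norm_table,
                            grand_index, poststratification_weights, scale_score)

# ---------------------------------------------------------------------------
# Post-stratification weights
# ---------------------------------------------------------------------------


def test_weights_identity_when_sample_matches_reference():
    cells = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
    ref = pd.Series({"A": 0.5, "B": 0.5})
    w = poststratification_weights(cells, ref)
    assert np.allclose(w, 1.0, atol=1e-12)


def test_weights_hand_ratio_case():
    # sample {A: 75%, B: 25%}, reference {A: 50%, B: 50%}
    cells = np.array(["A"] * 75 + ["B"] * 25, dtype=object)
    ref = pd.Series({"A": 0.5, "B": 0.5})
    w = poststratification_weights(cells, ref)
    # ratios 2/3 and 2 already sum to n, so rescaling is a no-op
    assert np.allclose(w[:75], 2.0 / 3.0, atol=1e-12)
    assert np.allclose(w[75:], 2.0, atol=1e-12)
    assert abs(w.sum() - 100) < 1e-9


def test_weights_zero_mass_reference_cell():
    cells = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
    ref = pd.Series({"A": 1.0, "B": 0.0})
    w = poststratification_weights(cells, ref)
    assert np.allclose(w[50:], 0.0)
    assert abs(w.sum() - 100) < 1e-9      # remainder rescaled to n


def test_weights_errors():
    ref = pd.Series({"A": 1.0})
    with pytest.raises(DataError, match="missing from reference"):
        poststratification_weights(np.array(["A", "B"], dtype=object), ref)
    with pytest.raises(DataError, match="empty"):
        poststratification_weights(np.array([], dtype=object), ref)


# ---------------------------------------------------------------------------
# Norm table construction
# ---------------------------------------------------------------------------


def test_median_maps_to_100():
    raw = np.arange(101, dtype=float)        # odd count, distinct, unit weights
    table = build_norm_table(raw, measure_id="m")
    assert scale_score(50.0, table) == pytest.approx(100.0, abs=1e-9)


def test_standard_normal_sample_recovers_linear_scaling(rng):
    raw = rng.standard_normal(10_000)
    table = build_norm_table(raw, measure_id="m")
    scaled = scale_score(raw, table)
    inner = np.abs(raw) < 2.5               # tails are percentile-clipped
    assert np.max(np.abs(scaled[inner] - (100 + 15 * raw[inner]))) < 1.5


def test_lower_raw_better_is_non_increasing(rng):
    raw = rng.normal(40, 10, 500)
    table = build_norm_table(raw, measure_id="tma", direction="lower_raw_better")
    assert np.all(np.diff(table.scaled_values) <= 0)
    # faster completion time scores above the mean
    assert scale_score(raw.min(), table) > 100 > scale_score(raw.max(), table)


def test_degenerate_and_floor_errors():
    with pytest.raises(NumericalError, match="identical"):
        build_norm_table(np.full(100, 7.0), measure_id="m")
    with pytest.raises(DataError, match="floor"):
        build_norm_table(np.arange(10, dtype=float), measure_id="m", min_distinct=50)


def test_scaled_values_clipped_at_five_sds():
    raw = np.arange(1_000_000, dtype=float)[:5000]
    table = build_norm_table(raw, measure_id="m")
    assert table.scaled_values.min() >= 100 - 75 and table.scaled_values.max() <= 100 + 75


# ---------------------------------------------------------------------------
# scale_score
# ---------------------------------------------------------------------------


def _toy_table():
    return NormTable(measure_id="toy", raw_values=np.array([0.0, 10.0, 20.0]),
                     scaled_values=np.array([95.0, 105.0, 110.0]))


def test_scale_score_knots_clamping_interpolation():
    t = _toy_table()
    assert scale_score(10.0, t) == 105.0            # exact knot
    assert scale_score(-5.0, t) == 95.0             # clamped below
    assert scale_score(99.0, t) == 110.0            # clamped above
    assert scale_score(5.0, t) == pytest.approx(100.0)   # midway 95..105


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
@settings(max_examples=100, deadline=None)
def test_scale_score_monotone_and_permutation_invariant(raws):
    t = _toy_table()
    arr = np.asarray(raws)
    out = scale_score(arr, t)
    order = np.argsort(arr, kind="mergesort")
    assert np.all(np.diff(out[order]) >= -1e-12)     # monotone in raw
    perm = np.random.default_rng(0).permutation(len(arr))
    assert np.allclose(scale_score(arr[perm], t), out[perm])


# ---------------------------------------------------------------------------
# Grand Index
# ---------------------------------------------------------------------------


def test_gi_symmetry_and_monotonicity(rng):
    sample = pd.DataFrame(rng.standard_normal((4000, 8)),
                          columns=[f"s{i}" for i in range(8)])
    scaler = NcptNormScaler().fit(sample)
    mid = {f"s{i}": 100.0 for i in range(8)}
    gi_mid = grand_index(mid, scaler.gi_table_)
    assert gi_mid == pytest.approx(100.0, abs=0.5)
    bumped = dict(mid)
    bumped["s3"] = 110.0
    assert grand_index(bumped, scaler.gi_table_) > gi_mid
    with pytest.raises(DataError, match="s1"):
        bad = dict(mid)
        bad["s1"] = float("nan")
        grand_index(bad, scaler.gi_table_)


def test_self_norming_property(rng):
    """A norm table applied to its own normative sample reproduces the
    mean-100 / SD-15 reference scale."""
    sample = pd.DataFrame(rng.standard_normal((10_000, 8)) * [3, 5, 1, 1, 9, 20, 4, 2]
                          + [20, 42, 6.5, 6, 35, 75, 15, 8],
                          columns=[f"s{i}" for i in range(8)])
    scaler = NcptNormScaler().fit(sample)
    scaled = scaler.transform(sample)
    for col in scaled.columns:
        assert abs(scaled[col].mean() - 100) < 0.5
        assert abs(scaled[col].std(ddof=1) - 15) < 0.5


def test_reweighting_identity_at_every_knot(rng):
    raw = rng.normal(50, 8, 2000)
    unweighted = build_norm_table(raw, measure_id="m")
    weighted = build_norm_table(raw, np.ones_like(raw), measure_id="m")
    assert np.allclose(unweighted.scaled_values, weighted.scaled_values, atol=1e-9)


def test_round_trip_preserves_percentile_ranks(rng):
    raw = rng.normal(0, 1, 1000)
    t1 = build_norm_table(raw, measure_id="m")
    scaled = scale_score(raw, t1)
    t2 = build_norm_table(scaled, measure_id="m2")
    rescaled = scale_score(scaled, t2)
    assert np.allclose(rescaled, scaled, atol=1e-9)


def test_norm_table_json_round_trip(tmp_path, rng):
    raw = rng.normal(10, 2, 200)
    table = build_norm_table(raw, measure_id="m", direction="higher_raw_better",
                             reference_meta={"note": "unit test"})
    path = tmp_path / "norm.json"
    table.to_json(str(path))
    back = NormTable.from_json(str(path))
    assert back.measure_id == "m"
    assert np.allclose(back.raw_values, table.raw_values)
    assert np.allclose(back.scaled_values, table.scaled_values)


def test_percentile_clipping_matches_closed_form():
    raw = np.arange(1, 101, dtype=float)
    table = build_norm_table(raw, measure_id="m")
    n = 100
    p_first = 0.5 / n                      # mid-rank of the minimum
    assert table.scaled_values[0] == pytest.approx(100 + 15 * norm.ppf(p_first))
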