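"""Centering, monthly aggregation, event profiles, z-scores, contrasts."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eleseason import (
    MonthlySeries,
    center_within_individual,
    gen_climate,
    gen_panel,
    gen_population,
    monthly_event_profile,
    monthly_group_means,
    pct_diff,
    zscore,
)
from eleseason.errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    MissingDataError,
    SchemaError,
)
from eleseason.xcorr import spearman
from conftest import make_panel


# -- within-individual centering -------------------------------------------


def test_centering_simple_example():
    panel = make_panel({"A": {1: 10.0, 2: 12.0, 3: 14.0}})
    res = center_within_individual(panel, "gcm")
    np.testing.assert_allclose(
        res.observations.sort_values("month")["value_centred"], [-2.0, 0.0, 2.0]
    )
    assert res.individual_means["A"] == 12.0


def test_centering_negate_flag_flips_sign():
    panel = make_panel({"A": {1: 10.0, 2: 14.0}})
    res = center_within_individual(panel, "gcm", negate=True)
    np.testing.assert_allclose(
        res.observations.sort_values("month")["value_centred"], [2.0, -2.0]
    )


def test_single_observation_individual_dropped(caplog):
    panel = make_panel({"A": {1: 10.0, 2: 12.0}, "B": {5: 99.0}})
    with caplog.at_level(logging.WARNING):
        res = center_within_individual(panel, "gcm")
    assert res.dropped == ["B"]
    assert "B" in caplog.text
    assert set(res.observations["id"]) == {"A"}


def test_centering_absent_variable_errors():
    panel = make_panel({"A": {1: 10.0, 2: 12.0}})
    with pytest.raises(InsufficientDataError):
        center_within_individual(panel, "weight")


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_centred_values_sum_to_zero_per_individual(seed):
    rng = np.random.default_rng(seed)
    data = {
        f"E{i}": {
            int(m): float(rng.normal(50, 20))
            for m in rng.choice(12, size=rng.integers(2, 13), replace=False) + 1
        }
        for i in range(rng.integers(1, 8))
    }
    res = center_within_individual(make_panel(data), "gcm")
    sums = res.observations.groupby("id")["value_centred"].sum()
    assert np.all(np.abs(sums.to_numpy()) < 1e-9)


def test_centering_idempotent():
    panel = make_panel({"A": {1: 3.0, 2: 7.0, 3: 5.0}, "B": {1: 0.0, 4: 4.0}})
    once = center_within_individual(panel, "gcm")
    recycled = once.observations.drop(columns=["value", "individual_mean"]).rename(
        columns={"value_centred": "value"}
    )
    twice = center_within_individual(recycled, "gcm")
    np.testing.assert_allclose(
        twice.observations["value_centred"].to_numpy(),
        once.observations["value_centred"].to_numpy(),
        atol=1e-12,
    )


def test_centering_invariant_to_constant_shift():
    panel = make_panel({"A": {1: 3.0, 2: 7.0}, "B": {1: 1.0, 2: 2.0, 5: 6.0}})
    shifted = panel.assign(value=panel["value"] + 100.0)
    a = center_within_individual(panel, "gcm").observations["value_centred"]
    b = center_within_individual(shifted, "gcm").observations["value_centred"]
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


# -- monthly group means ----------------------------------------------------


def test_group_mean_single_month():
    panel = make_panel({"A": {1: 1.0}, "B": {1: 2.0}, "C": {1: 3.0}})
    gm = monthly_group_means(panel, "gcm", ("sex",))
    series = gm.per_group[("female",)]
    assert series.value(1) == 2.0
    assert series.n_contributing[0] == 3


def test_pooled_mean_is_unweighted_across_groups():
    """A 3-member group and a 1-member group contribute equally."""
    rows = []
    for eid, sex, value in [
        ("A", "female", 9.0), ("B", "female", 10.0), ("C", "female", 11.0),
        ("D", "male", 20.0),
    ]:
        rows.append(
            {"id": eid, "sex": sex, "age_years": 30.0, "age_group": "17-44",
             "camp": "P", "month": 1, "variable": "gcm", "value": value}
        )
    gm = monthly_group_means(pd.DataFrame(rows), "gcm", ("sex",))
    assert gm.pooled.value(1) == 15.0  # (10 + 20) / 2, not the raw mean 12.5


def test_group_means_missing_grouping_field():
    panel = make_panel({"A": {1: 1.0}})
    with pytest.raises(SchemaError):
        monthly_group_means(panel, "gcm", ("herd",))


def test_group_means_match_cosine_oracle(noise_free_config):
    cfg = noise_free_config
    pop = gen_population(cfg)
    panel = gen_panel(pop, gen_climate(cfg), cfg)
    gm = monthly_group_means(panel, "gcm", ("sex", "age_group"))
    months = np.arange(1, 13)
    cosine = cfg.seasonal_amplitude_gcm * np.cos(
        2 * np.pi * (months - cfg.seasonal_peak_month_gcm) / 12
    )
    np.testing.assert_allclose(gm.pooled.values, cfg.gcm_baseline + cosine, atol=1e-10)


def test_monthly_means_shift_by_constant():
    panel = make_panel({"A": {1: 3.0, 2: 7.0}, "B": {1: 1.0, 2: 2.0}})
    gm0 = monthly_group_means(panel, "gcm", ("sex",))
    gm1 = monthly_group_means(panel.assign(value=panel["value"] + 5.0), "gcm", ("sex",))
    np.testing.assert_allclose(
        gm1.pooled.values[:2], gm0.pooled.values[:2] + 5.0, atol=1e-12
    )


def test_empty_months_propagate_as_missing():
    panel = make_panel({"A": {1: 3.0, 6: 7.0}})
    gm = monthly_group_means(panel, "gcm", ())
    assert np.isnan(gm.pooled.value(2))
    assert gm.pooled.n_contributing[1] == 0


def test_duplicate_observation_rejected():
    panel = make_panel({"A": {1: 3.0}})
    dup = pd.concat([panel, panel], ignore_index=True)
    with pytest.raises(SchemaError):
        monthly_group_means(dup, "gcm", ("sex",))


# -- demographic profiles ---------------------------------------------------


def _events(counts_by_month: dict, etype="birth", year=2000) -> pd.DataFrame:
    rows = [
        {"type": etype, "year": year, "month": m}
        for m, n in counts_by_month.items()
        for _ in range(n)
    ]
    return pd.DataFrame(rows, columns=["type", "year", "month"])


def test_flat_profile_ratio_one():
    events = _events({m: 2 for m in range(1, 13)})
    prof = monthly_event_profile(events, "birth", years_covered=1)
    np.testing.assert_allclose(prof.per_month_mean.values, 2.0)
    assert prof.max_min_ratio == 1.0
    assert prof.total_events == 24


def test_profile_ratio_and_extreme_months():
    counts = {m: 12 for m in range(1, 13)}
    counts[1], counts[7] = 18, 10
    prof = monthly_event_profile(_events(counts), "birth", years_covered=1)
    assert prof.max_month == 1 and prof.min_month == 7
    assert prof.max_min_ratio == pytest.approx(1.8)


def test_profile_conserves_total_counts():
    rng = np.random.default_rng(0)
    rows = [
        {"type": "death", "year": int(y), "month": int(m)}
        for y, m in zip(rng.integers(1990, 2000, 300), rng.integers(1, 13, 300))
    ]
    events = pd.DataFrame(rows)
    prof = monthly_event_profile(events, "death")
    assert prof.raw_counts.sum() == 300
    np.testing.assert_allclose(
        prof.per_month_mean.values * prof.years_covered, prof.raw_counts
    )


def test_profile_zero_events_reported_missing_not_error():
    events = _events({1: 3})
    prof = monthly_event_profile(events, "death", years_covered=2)
    assert prof.total_events == 0
    assert prof.max_min_ratio is None and prof.max_month is None


# -- z-scores ---------------------------------------------------------------


def _series(values):
    return MonthlySeries("x", "", np.asarray(values, dtype=float))


def test_zscore_three_months():
    vals = np.full(12, np.nan)
    vals[:3] = [1.0, 2.0, 3.0]
    z = zscore(_series(vals))
    np.testing.assert_allclose(z.values[:3], [-1.0, 0.0, 1.0])
    assert np.all(np.isnan(z.values[3:]))


def test_zscore_idempotent():
    rng = np.random.default_rng(1)
    z1 = zscore(_series(rng.normal(size=12)))
    z2 = zscore(z1)
    np.testing.assert_allclose(z2.values, z1.values, atol=1e-12)


def test_zscore_unit_moments():
    rng = np.random.default_rng(2)
    z = zscore(_series(rng.normal(10, 5, size=12)))
    assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.values.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_zscore_preserves_ranks():
    rng = np.random.default_rng(3)
    raw = _series(rng.normal(size=12))
    assert spearman(raw.values, zscore(raw).values) == pytest.approx(1.0)


def test_zscore_degenerate_and_short_inputs():
    with pytest.raises(DegenerateSeriesError):
        zscore(_series(np.full(12, 4.0)))
    nearly_empty = np.full(12, np.nan)
    nearly_empty[0] = 1.0
    with pytest.raises(InsufficientDataError):
        zscore(_series(nearly_empty))


# -- percent differences ----------------------------------------------------


def test_pct_diff_examples():
    vals = np.full(12, np.nan)
    vals[7], vals[0] = 183.6, 100.0  # August vs January
    s = _series(vals)
    assert pct_diff(s, 8, 1) == pytest.approx(83.6)
    assert pct_diff(s, 8, 8) == 0.0
    vals[8] = 104.9
    assert pct_diff(_series(vals), 9, 1) == pytest.approx(4.9)


def test_pct_diff_errors():
    vals = np.full(12, np.nan)
    vals[0], vals[1] = 0.0, 5.0
    s = _series(vals)
    with pytest.raises(MissingDataError):
        pct_diff(s, 3, 1)
    with pytest.raises(ZeroDivisionError):
        pct_diff(s, 2, 1)
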