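import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from mealpattern import (
    ProtocolConfig,
    ValidationError,
    cluster_bouts,
    feeding_rate,
    meals_table,
    segment_meals,
)
from .conftest import build_stream


def brute_force_partition(starts, durations, threshold_s):
    """Independent O(n^2) pairwise-gap oracle: connect every bout pair whose
    end-to-start gap is below the threshold, then take connected components."""
    starts = np.asarray(starts, dtype=float)
    ends = starts + np.asarray(durations, dtype=float)
    n = len(starts)
    if n == 0:
        return np.array([], dtype=int)
    gap = starts[None, :] - ends[:, None]  # gap[i, j] = start_j - end_i
    adj = (gap < threshold_s) & (np.arange(n)[None, :] > np.arange(n)[:, None])
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # relabel components in order of first appearance
    _, canonical = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(sorted(canonical))}
    return np.array([order[l] for l in labels])


def scan_labels(stream, cfg):
    clusters = cluster_bouts(stream, cfg)
    labels = np.empty(len(stream.bouts), dtype=int)
    for k, row in clusters.iterrows():
        labels[row["first_bout"] : row["last_bout"] + 1] = k
    return labels


def test_two_bouts_joined(cfg):
    """Gap 200 s < 300 s: one cluster, 0.06 g qualifies, 0.18 kCal."""
    stream = build_stream([0.0, 210.0], [10.0, 10.0], [0.03, 0.03])
    clusters = cluster_bouts(stream, cfg)
    assert len(clusters) == 1
    row = clusters.iloc[0]
    assert row["mass_g"] == pytest.approx(0.06)
    assert bool(row["qualifies"])
    assert row["size_kcal"] == pytest.approx(0.18)
    assert row["n_bouts"] == 2
    assert row["eating_time_s"] == pytest.approx(20.0)
    assert row["span_s"] == pytest.approx(220.0)


def test_two_bouts_split(cfg):
    """Gap 390 s >= 300 s: two clusters, neither reaches 0.050 g."""
    stream = build_stream([0.0, 400.0], [10.0, 10.0], [0.03, 0.03])
    clusters = cluster_bouts(stream, cfg)
    assert len(clusters) == 2
    assert not clusters["qualifies"].any()


def test_empty_stream(cfg):
    series = segment_meals(build_stream([], [], []), cfg)
    assert len(series.meals) == 0
    assert len(series.subthreshold) == 0
    assert len(series.imis) == 0


def test_single_subthreshold_bout_preserves_intake(cfg):
    series = segment_meals(build_stream([0.0], [30.0], [0.049]), cfg)
    assert len(series.meals) == 0
    assert len(series.subthreshold) == 1
    assert series.total_mass_g == pytest.approx(0.049)


def test_imi_70_minutes(cfg):
    """Meal ending 19:00, next starting 20:10 -> IMI of 70 min."""
    # meal 1: single bout 18:55-19:00; meal 2: single bout starting 20:10
    base = pd.Timestamp("2024-01-01 06:30")
    off1 = (pd.Timestamp("2024-01-01 18:55") - base).total_seconds()
    off2 = (pd.Timestamp("2024-01-01 20:10") - base).total_seconds()
    stream = build_stream([off1, off2], [300.0, 300.0], [0.1, 0.1])
    series = segment_meals(stream, cfg)
    assert len(series.meals) == 2
    assert series.imis.loc[0, "imi_s"] == pytest.approx(70 * 60)
    assert series.imis.loc[0, "photoperiod"] == "nocturnal"


def test_subthreshold_cluster_does_not_break_imi(cfg):
    """A nibble between two meals leaves one IMI spanning meal to meal."""
    stream = build_stream(
        [0.0, 1000.0, 2000.0], [60.0, 10.0, 60.0], [0.1, 0.01, 0.1]
    )
    series = segment_meals(stream, cfg)
    assert len(series.meals) == 2
    assert len(series.subthreshold) == 1
    assert len(series.imis) == 1
    # IMI runs from end of meal 1 (60 s) to start of meal 2 (2000 s)
    assert series.imis.loc[0, "imi_s"] == pytest.approx(1940.0)
    assert series.total_mass_g == pytest.approx(0.21)


def test_feeding_rate():
    assert feeding_rate(0.30, 120.0) == pytest.approx(0.0025)
    assert np.isnan(feeding_rate(0.30, 0.0))
    rates = feeding_rate(np.array([0.3, 0.3]), np.array([120.0, 0.0]))
    assert rates[0] == pytest.approx(0.0025) and np.isnan(rates[1])


def test_overlapping_bouts_rejected(cfg):
    stream = build_stream([0.0, 5.0], [10.0, 10.0], [0.1, 0.1])
    with pytest.raises(ValidationError, match="overlap"):
        cluster_bouts(stream, cfg)


@st.composite
def random_stream(draw, max_bouts=60):
    n = draw(st.integers(0, max_bouts))
    gaps = draw(
        st.lists(st.floats(0.001, 900.0, allow_nan=False), min_size=n, max_size=n)
    )
    durs = draw(
        st.lists(st.floats(0.5, 120.0, allow_nan=False), min_size=n, max_size=n)
    )
    masses = draw(
        st.lists(st.floats(0.0, 0.2, allow_nan=False), min_size=n, max_size=n)
    )
    starts = []
    t = 0.0
    for g, d in zip(gaps, durs):
        t += g
        starts.append(t)
        t += d
    return starts, durs, masses


@given(data=random_stream())
def test_scan_equals_pairwise_oracle(data):
    """Linear-scan clustering matches the O(n^2) pairwise-gap oracle."""
    starts, durs, masses = data
    cfg = ProtocolConfig()
    stream = build_stream(starts, durs, masses)
    expected = brute_force_partition(starts, durs, cfg.imi_threshold_s)
    np.testing.assert_array_equal(scan_labels(stream, cfg), expected)


@given(data=random_stream())
def test_mass_conservation_and_limits(data):
    """Total bout mass is conserved; extreme thresholds give the two limits."""
    starts, durs, masses = data
    stream = build_stream(starts, durs, masses)
    cfg = ProtocolConfig()
    series = segment_meals(stream, cfg)
    assert series.total_mass_g == pytest.approx(float(np.sum(masses)), abs=1e-12)
    n = len(starts)
    tiny = ProtocolConfig(imi_threshold_s=1e-9)
    huge = ProtocolConfig(imi_threshold_s=1e8)
    assert len(cluster_bouts(stream, tiny)) == n
    assert len(cluster_bouts(stream, huge)) == (1 if n else 0)


@given(data=random_stream(max_bouts=40))
def test_cluster_count_monotone_in_threshold(data):
    starts, durs, masses = data
    stream = build_stream(starts, durs, masses)
    counts = [
        len(cluster_bouts(stream, ProtocolConfig(imi_threshold_s=thr)))
        for thr in (30.0, 120.0, 300.0, 600.0, 1200.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_meal_count_can_increase_with_threshold(cfg):
    """With a minimum meal size, merging two subthreshold clusters can
    create a meal, so meal count is not monotone in the threshold."""
    stream = build_stream([0.0, 400.0], [10.0, 10.0], [0.03, 0.03])
    n_meals = lambda thr: len(
        segment_meals(stream, ProtocolConfig(imi_threshold_s=thr)).meals
    )
    assert n_meals(300.0) == 0  # two nibbles
    assert n_meals(500.0) == 1  # merged cluster reaches 0.06 g


def test_eating_time_vs_span_invariant(small_cohort, cfg):
    streams, _ = small_cohort
    for s in streams.values():
        clusters = cluster_bouts(s, cfg)
        multi = clusters[clusters["n_bouts"] > 1]
        assert (multi["eating_time_s"] <= multi["span_s"] + 1e-9).all()
        single = clusters[clusters["n_bouts"] == 1]
        np.testing.assert_allclose(single["eating_time_s"], single["span_s"], atol=1e-6)


def test_duration_mode_switch(small_cohort):
    streams, _ = small_cohort
    s = next(iter(streams.values()))
    m_eat = segment_meals(s, ProtocolConfig(meal_duration_mode="eating_time")).meals
    m_span = segment_meals(s, ProtocolConfig(meal_duration_mode="span")).meals
    np.testing.assert_allclose(m_eat["duration_s"], m_eat["eating_time_s"])
    np.testing.assert_allclose(m_span["duration_s"], m_span["span_s"])


def test_meals_table_schema(small_cohort, cfg):
    streams, _ = small_cohort
    s = next(iter(streams.values()))
    table = meals_table(segment_meals(s, cfg))
    assert list(table.columns) == [
        "animal_id", "meal_index", "t_first", "t_last", "n_bouts", "mass_g",
        "size_kcal", "eating_time_s", "span_s", "qualifies", "photoperiod",
        "imi_to_next_s",
    ]
    assert (table["imi_to_next_s"].dropna() >= cfg.imi_threshold_s).all()
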