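import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosim import (
    RunRecord,
    detect_clustering_time,
    detect_migration_time,
    summarize_population,
)
from mitosim.observables import records_to_dataframe


def _record(seed=0, cl=20.0, cl_cens=False, mg=40.0, mg_cens=False, neck=1.5):
    return RunRecord(
        seed=seed,
        scenario="wild_type_cib",
        clustering_time_min=cl,
        clustering_censored=cl_cens,
        migration_time_min=mg,
        migration_censored=mg_cens,
        mean_cmt_length_um=2.3,
        final_neck_to_nucleus_um=neck,
        f_c_cell=1.0,
        n_bodies_final=1,
    )


# ---------------- clustering detection ----------------------------------
def test_single_founder_clusters_at_zero():
    t, censored = detect_clustering_time(np.array([]), np.array([]), 1, 60.0)
    assert t == 0.0 and not censored


def test_clustering_time_is_final_merge():
    times = np.array([2.0, 8.0, 21.4])
    nrem = np.array([3, 2, 1])
    t, censored = detect_clustering_time(times, nrem, 4, 60.0)
    assert t == 21.4 and not censored


def test_incomplete_fusion_censored_at_run_end():
    t, censored = detect_clustering_time(np.array([5.0]), np.array([13]), 14, 57.0)
    assert t == 57.0 and censored


# ---------------- migration detection -----------------------------------
def test_migration_threshold_crossing():
    times = np.arange(0.0, 60.0, 0.5)
    dist = np.linspace(-3.0, 2.0, times.size)
    t, censored = detect_migration_time(times, dist, threshold_um=1.0, cutoff_min=60.0)
    assert not censored
    assert dist[np.searchsorted(times, t)] >= 1.0


def test_migration_censored_at_cutoff():
    times = np.arange(0.0, 60.0, 1.0)
    dist = np.full_like(times, -2.0)
    t, censored = detect_migration_time(times, dist, 1.0, 60.0)
    assert t == 60.0 and censored


def test_start_past_threshold_is_zero():
    t, censored = detect_migration_time(np.array([0.0, 1.0]), np.array([1.5, 1.6]), 1.0, 60.0)
    assert t == 0.0 and not censored


# ---------------- population summaries ----------------------------------
def test_two_point_mean_and_sem():
    recs = [_record(mg=30.0), _record(seed=1, mg=40.0)]
    s = summarize_population(recs)
    assert s.mean_migration_min == pytest.approx(35.0)
    assert s.sem_migration_min == pytest.approx(5.0)


def test_all_censored_population():
    recs = [
        _record(cl=60.0, cl_cens=True, mg=60.0, mg_cens=True, neck=-2.0)
        for _ in range(3)
    ]
    s = summarize_population(recs)
    assert s.fraction_complete_fusion == 0.0
    assert s.fraction_proper_migration == 0.0
    assert math.isnan(s.mean_migration_min)


def test_fraction_complete():
    recs = [_record(seed=i) for i in range(98)] + [
        _record(seed=98 + i, cl=60.0, cl_cens=True) for i in range(2)
    ]
    s = summarize_population(recs)
    assert s.fraction_complete_fusion == pytest.approx(0.98)


def test_empty_population_rejected():
    with pytest.raises(ValueError):
        summarize_population([])


@settings(max_examples=25, deadline=None)
@given(st.permutations(list(range(8))))
def test_summary_invariant_under_record_order(perm):
    recs = [
        _record(seed=i, cl=10.0 + i, mg=30.0 + 2 * i, neck=-2.0 + 0.5 * i)
        for i in range(8)
    ]
    base = summarize_population(recs)
    shuffled = summarize_population([recs[i] for i in perm])
    assert base.mean_clustering_min == pytest.approx(shuffled.mean_clustering_min)
    assert base.mean_migration_min == pytest.approx(shuffled.mean_migration_min)
    assert base.distance_histogram == shuffled.distance_histogram


def test_dataframe_round_trip_columns():
    df = records_to_dataframe([_record(), _record(seed=1)])
    assert len(df) == 2
    assert {"seed", "clustering_time_min", "migration_time_min", "f_c_cell"} <= set(df.columns)
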