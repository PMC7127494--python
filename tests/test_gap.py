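import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distances import distance_matrix
from barcodegap.gap import (
    GapError,
    PairPartition,
    distance_histogram,
    gap_criterion_fold,
    gap_criterion_minmax,
    gap_report,
    partition_distances,
    summary_table,
)
from barcodegap.simulate import coi_like_config, simulate_dataset

from conftest import make_dataset

pools = st.lists(st.floats(0, 0.5, allow_nan=False), min_size=1, max_size=60)


def make_partition(intra, inter):
    return PairPartition(intra={"sp1": list(intra)}, inter={("sp1", "sp2"): list(inter)})


def test_partition_two_by_two_counting():
    seqs = {"a1": "AAAA" * 100, "a2": "AAAT" * 100, "b1": "GGGG" * 100, "b2": "GGGC" * 100}
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    ds = make_dataset(seqs, species_by_id=species)
    m = distance_matrix(ds, "p_distance")
    p = partition_distances(m, ds.records)
    assert {sp: len(v) for sp, v in p.intra.items()} == {"A": 1, "B": 1}
    assert len(p.inter[("A", "B")]) == 4


def test_partition_single_species_has_no_inter():
    ds = make_dataset({"a": "A" * 400, "b": "A" * 400})
    m = distance_matrix(ds, "p_distance")
    p = partition_distances(m, ds.records)
    assert p.pooled_inter == []
    assert len(p.pooled_intra) == 1


def test_partition_study_size_counting():
    """20+20 specimens give 190+190 intraspecific and 400 interspecific pairs."""
    ds, _ = simulate_dataset(coi_like_config(2))
    m = distance_matrix(ds, "k2p")
    p = partition_distances(m, ds.records, {"P_canaliculata", "P_maculata"})
    assert sorted(len(v) for v in p.intra.values()) == [190, 190]
    assert len(p.pooled_inter) == 400
    # pooled counts cover every valid focal pair exactly once
    assert len(p.pooled_intra) + len(p.pooled_inter) == 190 + 190 + 400


def test_partition_requires_species_labels():
    ds = make_dataset({"a": "A" * 400, "b": "A" * 400})
    m = distance_matrix(ds, "k2p")
    records = tuple()  # no metadata for the matrix ids
    with pytest.raises(GapError, match="species"):
        partition_distances(m, records)


def test_focal_filter_drops_congener_pairs():
    ds, _ = simulate_dataset(coi_like_config(2))
    m = distance_matrix(ds, "k2p")
    full = partition_distances(m, ds.records)
    focal = partition_distances(m, ds.records, {"P_canaliculata", "P_maculata"})
    assert "P_scalaris" in full.intra and "P_scalaris" not in focal.intra
    assert all("P_scalaris" not in pair for pair in focal.inter)


def test_minmax_gap_on_printed_extremes():
    """Study arithmetic: 11.0 - 4.9 = 6.1 and 2.2 - 0.6 = 1.6 (percent)."""
    coi = make_partition([0.0, 0.024, 0.049], [0.110, 0.112, 0.119])
    gap_full, _ = gap_criterion_minmax(coi)
    assert 100 * gap_full == pytest.approx(6.1)
    ssu = make_partition([0.0, 0.003, 0.006], [0.022, 0.024, 0.026])
    gap_full, _ = gap_criterion_minmax(ssu)
    assert 100 * gap_full == pytest.approx(1.6)


def test_minmax_gap_boundary_overlap_is_zero():
    gap_full, _ = gap_criterion_minmax(make_partition([0.01, 0.02], [0.02, 0.03]))
    assert gap_full == 0.0


def test_minmax_trim_removes_floor_fraction():
    intra = [0.01] * 19 + [0.30]  # floor(0.05*20) = 1 -> drops the outlier
    inter = [0.05] * 19 + [0.001]
    gap_full, gap_trimmed = gap_criterion_minmax(make_partition(intra, inter))
    assert gap_full == pytest.approx(0.001 - 0.30)
    assert gap_trimmed == pytest.approx(0.05 - 0.01)


def test_fold_ratio_matches_printed_sixteens_arithmetic():
    """Mean inter 2.4% over pooled mean intra 0.2% is the printed 12-fold."""
    p = make_partition([0.003, 0.001], [0.024, 0.024])
    ratio, passes = gap_criterion_fold(p)
    assert ratio == pytest.approx(12.0)
    assert passes


def test_fold_ratio_boundary_inclusive():
    ratio, passes = gap_criterion_fold(make_partition([0.01, 0.03], [0.2, 0.2]))
    assert ratio == pytest.approx(10.0)
    assert passes


def test_fold_ratio_zero_intra_is_infinite_pass():
    ratio, passes = gap_criterion_fold(make_partition([0.0, 0.0], [0.1]))
    assert math.isinf(ratio)
    assert passes


def test_empty_pools_are_undefined():
    with pytest.raises(GapError):
        gap_criterion_minmax(PairPartition(intra={}, inter={("a", "b"): [0.1]}))
    with pytest.raises(GapError):
        gap_criterion_fold(PairPartition(intra={"a": [0.1]}, inter={}))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(intra=pools, inter=pools, trim=st.floats(0, 0.49))
def test_trimmed_gap_never_smaller_than_full(intra, inter, trim):
    gap_full, gap_trimmed = gap_criterion_minmax(make_partition(intra, inter), trim)
    assert gap_trimmed >= gap_full


@settings(max_examples=100, deadline=None, derandomize=True)
@given(intra=pools, inter=pools, c=st.floats(0.01, 5.0))
def test_scaling_distances_scales_gap_not_fold(intra, inter, c):
    base = make_partition(intra, inter)
    scaled = make_partition([c * d for d in intra], [c * d for d in inter])
    g0, t0 = gap_criterion_minmax(base)
    g1, t1 = gap_criterion_minmax(scaled)
    assert g1 == pytest.approx(c * g0, rel=1e-9, abs=1e-12)
    assert t1 == pytest.approx(c * t0, rel=1e-9, abs=1e-12)
    r0, _ = gap_criterion_fold(base)
    r1, _ = gap_criterion_fold(scaled)
    if not math.isinf(r0):
        assert r1 == pytest.approx(r0, rel=1e-9)


def test_summary_table_all_identical_is_zero():
    p = make_partition([0.0, 0.0], [0.0])
    df = summary_table(p)
    assert (df[["min_pct", "mean_pct", "max_pct"]] == 0.0).all().all()


def test_summary_table_matches_hand_computation():
    p = PairPartition(
        intra={"A": [0.01, 0.02, 0.03], "B": [0.0]},
        inter={("A", "B"): [0.10, 0.12]},
    )
    df = summary_table(p).set_index("taxon")
    assert df.loc["A", ["min_pct", "mean_pct", "max_pct"]].tolist() == [1.0, 2.0, 3.0]
    assert df.loc["pooled", "mean_pct"] == pytest.approx(11.0)
    assert df.loc["pooled", "n_pairs"] == 2


def test_histogram_bins_left_closed():
    h = distance_histogram([0.01, 0.011], 0.005)
    assert len(h) == 1
    assert h.iloc[0]["bin_start"] == pytest.approx(0.01)
    assert h.iloc[0]["bin_end"] == pytest.approx(0.015)
    assert h.iloc[0]["count"] == 2


def test_histogram_empty_pool():
    assert distance_histogram([], 0.01).empty


def test_histogram_conserves_counts(rng):
    pool = list(rng.random(500) * 0.3)
    h = distance_histogram(pool, 0.004)
    assert h["count"].sum() == 500


def test_gap_report_coherent_on_synthetic_data():
    ds, _ = simulate_dataset(coi_like_config(9))
    m = distance_matrix(ds, "k2p")
    p = partition_distances(m, ds.records, {"P_canaliculata", "P_maculata"})
    rep = gap_report(p)
    assert rep.gap_full == pytest.approx(rep.min_inter - rep.max_intra)
    assert rep.gap_trimmed >= rep.gap_full
    assert rep.fold_ratio == pytest.approx(rep.mean_inter / rep.mean_intra)
    assert rep.gap_full > 0  # inter >> intra by construction
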