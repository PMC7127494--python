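import math

import numpy as np
import pytest

from barcodegap.dataio import SpecimenRecord
from barcodegap.distances import DistanceMatrix, distance_matrix
from barcodegap.gap import PairPartition, partition_distances
from barcodegap.identify import (
    IdentificationError,
    ThresholdSpec,
    all_species_barcode,
    best_close_match,
    best_match,
    identification_summary,
    identify_all,
    intraspecific_threshold,
)
from barcodegap.simulate import coi_like_config, simulate_dataset


def matrix_from(ids, dist, invalid=()):
    """Symmetric DistanceMatrix from a {frozenset pair: distance} mapping."""
    n = len(ids)
    values = np.zeros((n, n))
    valid = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((ids[i], ids[j]))
            values[i, j] = values[j, i] = dist[key]
            if key in invalid:
                valid[i, j] = valid[j, i] = False
    return DistanceMatrix("k2p", tuple(ids), values, valid, min_overlap=0)


def records_for(species_by_id, roles=None):
    roles = roles or {}
    return tuple(
        SpecimenRecord(sid, sp, roles.get(sid, "query")) for sid, sp in species_by_id.items()
    )


@pytest.fixture
def toy():
    """q nearest a conspecific; x is an allospecific decoy further away."""
    ids = ["q", "a1", "a2", "x"]
    dist = {
        frozenset(("q", "a1")): 0.01,
        frozenset(("q", "a2")): 0.02,
        frozenset(("q", "x")): 0.10,
        frozenset(("a1", "a2")): 0.015,
        frozenset(("a1", "x")): 0.11,
        frozenset(("a2", "x")): 0.12,
    }
    species = {"q": "A", "a1": "A", "a2": "A", "x": "B"}
    return matrix_from(ids, dist), records_for(species)


def test_threshold_covers_requested_fraction():
    p = PairPartition(intra={"A": [0.01 * k for k in range(1, 21)]}, inter={})
    t = intraspecific_threshold(p, coverage=0.95)
    assert t.value == pytest.approx(0.19)  # 19/20 of values lie at or below
    assert t.n_intra == 20


def test_threshold_degenerate_all_zero_pool():
    p = PairPartition(intra={"A": [0.0] * 7}, inter={})
    assert intraspecific_threshold(p).value == 0.0


def test_threshold_empty_pool_undefined():
    with pytest.raises(IdentificationError, match="empty"):
        intraspecific_threshold(PairPartition(intra={}, inter={}))


def test_best_match_nearest_conspecific_correct(toy):
    m, records = toy
    res = best_match("q", m, records)
    assert res.outcome == "correct"
    assert res.matched_species == {"A"}
    assert res.best_distance == pytest.approx(0.01)


def test_best_match_exact_tie_is_ambiguous():
    ids = ["q", "a", "b"]
    dist = {
        frozenset(("q", "a")): 0.02,
        frozenset(("q", "b")): 0.02,
        frozenset(("a", "b")): 0.05,
    }
    m = matrix_from(ids, dist)
    res = best_match("q", m, records_for({"q": "A", "a": "A", "b": "B"}))
    assert res.outcome == "ambiguous"
    assert res.matched_species == {"A", "B"}


def test_best_match_nearest_allospecific_incorrect(toy):
    m, records = toy
    res = best_match("x", m, records)  # x's nearest is a1 (species A)
    assert res.outcome == "incorrect"


def test_best_match_singleton_species_cannot_be_correct(rng):
    """A query whose species has no other representative never scores correct."""
    for _ in range(20):
        ids = ["solo", "a1", "a2", "b1"]
        vals = rng.random(6) * 0.2
        dist = dict(
            zip(
                [frozenset(p) for p in
                 [("solo", "a1"), ("solo", "a2"), ("solo", "b1"), ("a1", "a2"), ("a1", "b1"), ("a2", "b1")]],
                vals,
            )
        )
        m = matrix_from(ids, dist)
        res = best_match("solo", m, records_for({"solo": "S", "a1": "A", "a2": "A", "b1": "B"}))
        assert res.outcome != "correct"


def test_best_match_requires_valid_comparison():
    ids = ["q", "a"]
    dist = {frozenset(("q", "a")): 0.01}
    m = matrix_from(ids, dist, invalid={frozenset(("q", "a"))})
    with pytest.raises(IdentificationError, match="no valid comparisons"):
        best_match("q", m, records_for({"q": "A", "a": "A"}))


def test_best_close_match_above_threshold_is_no_match(toy):
    m, records = toy
    t = ThresholdSpec(coverage=0.95, value=0.005, n_intra=10)
    res = best_close_match("q", m, records, t)
    assert res.outcome == "no_match"
    assert res.matched_species == frozenset()


def test_best_close_match_threshold_inclusive_vs_strict(toy):
    m, records = toy
    t = ThresholdSpec(coverage=0.95, value=0.01, n_intra=10)
    assert best_close_match("q", m, records, t).outcome == "correct"
    assert best_close_match("q", m, records, t, strict=True).outcome == "no_match"


def test_best_close_match_with_infinite_threshold_reduces_to_best_match(toy):
    m, records = toy
    t = ThresholdSpec(coverage=0.95, value=math.inf, n_intra=10)
    for qid in m.ids:
        assert best_close_match(qid, m, records, t).outcome == best_match(qid, m, records).outcome


def test_all_species_barcode_outcomes(toy):
    m, records = toy
    # only conspecifics within 0.05 of q -> correct
    t = ThresholdSpec(0.95, 0.05, 10)
    assert all_species_barcode("q", m, records, t).outcome == "correct"
    # everything within 0.2 -> conspecific and allospecific -> ambiguous
    t = ThresholdSpec(0.95, 0.2, 10)
    assert all_species_barcode("q", m, records, t).outcome == "ambiguous"
    # nothing within 0.001 -> no_match
    t = ThresholdSpec(0.95, 0.001, 10)
    assert all_species_barcode("q", m, records, t).outcome == "no_match"
    # x sees only species A within 0.115 -> incorrect
    t = ThresholdSpec(0.95, 0.115, 10)
    assert all_species_barcode("x", m, records, t).outcome == "incorrect"


def test_queries_only_mode_restricts_candidates(toy):
    m, _ = toy
    records = records_for(
        {"q": "A", "a1": "A", "a2": "A", "x": "B"},
        roles={"a1": "reference", "a2": "reference", "x": "reference"},
    )
    res = best_match("q", m, records, queries_only=True)
    assert res.outcome == "correct"
    results = identify_all(m, records, ThresholdSpec(0.95, 0.05, 10), queries_only=True)
    assert {r.query_id for r in results} == {"q"}


def test_identification_invariant_under_sequence_permutation(rng):
    ds, _ = simulate_dataset(coi_like_config(13, n_per_species=6))
    m = distance_matrix(ds, "k2p")
    part = partition_distances(m, ds.records)
    t = intraspecific_threshold(part)
    base = {(r.query_id, r.criterion): r.outcome for r in identify_all(m, ds.records, t)}
    order = list(rng.permutation(ds.ids))
    ds_perm = ds.subset(order)
    m_perm = distance_matrix(ds_perm, "k2p")
    perm = {(r.query_id, r.criterion): r.outcome for r in identify_all(m_perm, ds_perm.records, t)}
    assert base == perm


def test_summary_percentages():
    ds, _ = simulate_dataset(coi_like_config(5, n_per_species=6))
    m = distance_matrix(ds, "k2p")
    part = partition_distances(m, ds.records)
    results = identify_all(m, ds.records, partition=part)
    df = identification_summary(results)
    assert len(df) == 3
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    assert df[pct_cols].sum(axis=1).tolist() == pytest.approx([100.0] * 3, abs=0.2)


def test_summary_thirty_four_of_thirty_five_is_97_1():
    from barcodegap.identify import IdentificationResult

    results = [
        IdentificationResult(f"q{i}", "best_close_match", "correct" if i else "no_match", 0.01, frozenset({"A"}))
        for i in range(35)
    ]
    df = identification_summary(results)
    assert df.iloc[0]["correct_pct"] == pytest.approx(97.1)
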