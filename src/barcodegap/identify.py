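"""Similarity-based species identification (best match, best close match,
all species barcode).

Every sequence in the dataset acts as a query against all others (self
excluded); alternatively only query-role specimens are scored.  The two
thresholded criteria use the distance below which a chosen fraction
(default 95%) of all pooled intraspecific distances fall.  The threshold
comparison is inclusive by default (a match at exactly the threshold
passes); a strict mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import SpecimenRecord
from .distances import DistanceMatrix
from .gap import PairPartition

BEST_MATCH = "best_match"
BEST_CLOSE_MATCH = "best_close_match"
ALL_SPECIES_BARCODE = "all_species_barcode"
CRITERIA = (BEST_MATCH, BEST_CLOSE_MATCH, ALL_SPECIES_BARCODE)

OUTCOMES = ("correct", "ambiguous", "incorrect", "no_match")


class IdentificationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSpec:
    """Distance covering a given fraction of pooled intraspecific distances."""

    coverage: float
    value: float
    n_intra: int


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    criterion: str
    outcome: str
    best_distance: float | None
    matched_species: frozenset[str]


def intraspecific_threshold(p: PairPartition, coverage: float = 0.95) -> ThresholdSpec:
    """Smallest pooled intraspecific distance t with P(d <= t) >= coverage."""
    pool = sorted(p.pooled_intra)
    if not pool:
        raise IdentificationError("threshold undefined: empty intraspecific pool")
    n = len(pool)
    for i, t in enumerate(pool):
        # count of values <= t is at least i+1; ties make it larger but the
        # first index reaching coverage still yields the smallest such t
        if (i + 1) / n >= coverage:
            return ThresholdSpec(coverage=coverage, value=t, n_intra=n)
    return ThresholdSpec(coverage=coverage, value=pool[-1], n_intra=n)


def _candidates(
    query_id: str, m: DistanceMatrix, species: dict[str, str], queries_only: bool, roles: dict[str, str]
) -> list[tuple[str, float]]:
    qi = m.ids.index(query_id)
    out = []
    for j, sid in enumerate(m.ids):
        if sid == query_id or not m.valid[qi, j]:
            continue
        if queries_only and roles.get(sid) != "reference":
            continue
        out.append((sid, float(m.values[qi, j])))
    return out


def _prep(records) -> tuple[dict[str, str], dict[str, str]]:
    species = {r.specimen_id: r.species_label for r in records}
    roles = {r.specimen_id: r.role for r in records}
    return species, roles


def best_match(
    query_id: str,
    m: DistanceMatrix,
    records,
    queries_only: bool = False,
) -> IdentificationResult:
    """Judge the query by the species of its nearest sequence(s).

    Exact ties at the minimum distance pool their species; more than one
    species at the minimum is ambiguous regardless of input order.
    """
    species, roles = _prep(records)
    cands = _candidates(query_id, m, species, queries_only, roles)
    if not cands:
        raise IdentificationError(f"{query_id}: no valid comparisons")
    best = min(d for _, d in cands)
    matched = frozenset(species[sid] for sid, d in cands if d == best)
    truth = species[query_id]
    if matched == {truth}:
        outcome = "correct"
    elif len(matched) > 1:
        outcome = "ambiguous"
    else:
        outcome = "incorrect"
    return IdentificationResult(query_id, BEST_MATCH, outcome, best, matched)


def best_close_match(
    query_id: str,
    m: DistanceMatrix,
    records,
    t: ThresholdSpec,
    queries_only: bool = False,
    strict: bool = False,
) -> IdentificationResult:
    """Best match, demoted to no_match when the best distance exceeds the threshold."""
    res = best_match(query_id, m, records, queries_only)
    passes = res.best_distance < t.value if strict else res.best_distance <= t.value
    if not passes:
        return IdentificationResult(query_id, BEST_CLOSE_MATCH, "no_match", res.best_distance, frozenset())
    return IdentificationResult(query_id, BEST_CLOSE_MATCH, res.outcome, res.best_distance, res.matched_species)


def all_species_barcode(
    query_id: str,
    m: DistanceMatrix,
    records,
    t: ThresholdSpec,
    queries_only: bool = False,
    strict: bool = False,
) -> IdentificationResult:
    """Judge the query by the species set of every sequence within the threshold."""
    species, roles = _prep(records)
    cands = _candidates(query_id, m, species, queries_only, roles)
    if not cands:
        raise IdentificationError(f"{query_id}: no valid comparisons")
    best = min(d for _, d in cands)
    within = [
        (sid, d) for sid, d in cands if (d < t.value if strict else d <= t.value)
    ]
    matched = frozenset(species[sid] for sid, _ in within)
    truth = species[query_id]
    if not matched:
        outcome = "no_match"
    elif matched == {truth}:
        outcome = "correct"
    elif truth in matched or len(matched) > 1:
        outcome = "ambiguous"
    else:
        outcome = "incorrect"
    return IdentificationResult(query_id, ALL_SPECIES_BARCODE, outcome, best, matched)


def identify_all(
    m: DistanceMatrix,
    records,
    t: ThresholdSpec | None = None,
    coverage: float = 0.95,
    queries_only: bool = False,
    strict: bool = False,
    partition: PairPartition | None = None,
) -> list[IdentificationResult]:
    """Run all three criteria for every eligible query.

    The threshold defaults to the intraspecific coverage threshold computed
    from ``partition`` (which must then be supplied).
    """
    if t is None:
        if partition is None:
            raise IdentificationError("need a ThresholdSpec or a PairPartition")
        t = intraspecific_threshold(partition, coverage)
    roles = {r.specimen_id: r.role for r in records}
    queries = [sid for sid in m.ids if not queries_only or roles.get(sid) == "query"]
    results = []
    for qid in queries:
        results.append(best_match(qid, m, records, queries_only))
        results.append(best_close_match(qid, m, records, t, queries_only, strict))
        results.append(all_species_barcode(qid, m, records, t, queries_only, strict))
    return results


def identification_summary(results: list[IdentificationResult]) -> pd.DataFrame:
    """Percentage of each outcome per criterion; rows sum to 100%."""
    if not results:
        raise IdentificationError("no results to summarise")
    df = pd.DataFrame(
        [{"criterion": r.criterion, "outcome": r.outcome} for r in results]
    )
    rows = []
    for crit, grp in df.groupby("criterion", sort=False):
        n = len(grp)
        counts = grp["outcome"].value_counts()
        row = {"criterion": crit, "n_queries": n}
        for outcome in OUTCOMES:
            row[f"{outcome}_pct"] = round(100.0 * counts.get(outcome, 0) / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: list[IdentificationResult], t: ThresholdSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcriterion\toutcome\tbest_distance_pct\tmatched_species\tthreshold_pct\n")
        for r in results:
            d = "" if r.best_distance is None else f"{100 * r.best_distance:.2f}"
            sp = ",".join(sorted(r.matched_species))
            fh.write(f"{r.query_id}\t{r.criterion}\t{r.outcome}\t{d}\t{sp}\t{100 * t.value:.2f}\n")
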