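"""Pairwise p-distances and Kimura two-parameter distances.

Comparison of two aligned sequences uses pairwise deletion: a column enters
the comparison only when both sequences carry an unambiguous base (A/C/G/T);
gaps and IUPAC ambiguity codes are excluded entirely.  Mismatches split into
transitions (A<->G, C<->T) and transversions (everything else), giving the
proportions P and Q from which the K2P distance is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Pairs whose unambiguous overlap falls below a minimum (default 300 sites) or
whose K2P logarithm argument is non-positive (saturation) are flagged invalid
and are skipped by all downstream pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataio import AlignedDataset

#: Base encoding: A,G share the purine bit-group; C,T the pyrimidine group,
#: so two unequal codes are a transition iff code >> 1 matches.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_INVALID = 255

DEFAULT_MIN_OVERLAP = 300


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class PairComparison:
    """Site tally for one sequence pair under pairwise deletion."""

    overlap: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.overlap

    @property
    def Q(self) -> float:
        return self.transversions / self.overlap


def encode_alignment(ds: AlignedDataset) -> np.ndarray:
    """(n, columns) uint8 matrix; non-ACGT characters get the invalid code."""
    lut = np.full(256, _INVALID, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    rows = [
        lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)] for seq in ds.sequences.values()
    ]
    return np.vstack(rows)


def _compare_rows(a: np.ndarray, b: np.ndarray) -> PairComparison:
    both = (a != _INVALID) & (b != _INVALID)
    overlap = int(both.sum())
    diff = both & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    return PairComparison(overlap=overlap, transitions=ts, transversions=int(diff.sum()) - ts)


def compare_pair(seq_a: str, seq_b: str) -> PairComparison:
    """Tally overlap, transitions and transversions for two aligned strings."""
    if len(seq_a) != len(seq_b):
        raise DistanceError(f"unequal lengths: {len(seq_a)} vs {len(seq_b)}")
    lut = np.full(256, _INVALID, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    a = lut[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = lut[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    return _compare_rows(a, b)


def p_distance(cmp: PairComparison) -> float:
    """Uncorrected proportion of mismatching sites."""
    if cmp.overlap == 0:
        raise DistanceError("p-distance undefined: zero overlap")
    return (cmp.transitions + cmp.transversions) / cmp.overlap


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition/transversion mismatch proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise DistanceError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
    if P == 0.0 and Q == 0.0:
        return 0.0
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(cmp: PairComparison) -> float:
    """Kimura two-parameter distance; raises on saturation.

    Returns 0 exactly when there are no mismatches.
    """
    if cmp.overlap == 0:
        raise DistanceError("K2P distance undefined: zero overlap")
    return k2p_from_proportions(cmp.P, cmp.Q)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with validity flags.

    ``values[i, j]`` is in substitutions per site; ``valid[i, j]`` is False
    where the overlap fell below ``min_overlap`` or the K2P correction
    saturated.  The diagonal is zero and valid.
    """

    model: str  # "p_distance" | "k2p"
    ids: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray
    min_overlap: int

    def get(self, id_a: str, id_b: str) -> tuple[float, bool]:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j]), bool(self.valid[i, j])


def distance_matrix(
    ds: AlignedDataset, model: str = "k2p", min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-against-all distances under pairwise deletion with overlap filter."""
    if model not in ("p_distance", "k2p"):
        raise DistanceError(f"unknown model {model!r}")
    enc = encode_alignment(ds)
    n = enc.shape[0]
    values = np.zeros((n, n), dtype=float)
    valid = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            cmp = _compare_rows(enc[i], enc[j])
            ok = cmp.overlap >= min_overlap and cmp.overlap > 0
            d = np.nan
            if ok:
                try:
                    d = p_distance(cmp) if model == "p_distance" else k2p_distance(cmp)
                except DistanceError:
                    ok = False
            values[i, j] = values[j, i] = d if ok else np.nan
            valid[i, j] = valid[j, i] = ok
    return DistanceMatrix(
        model=model,
        ids=tuple(ds.ids),
        values=values,
        valid=valid,
        min_overlap=min_overlap,
    )


def write_matrix(m: DistanceMatrix, path, percent: bool = True) -> None:
    """Square tab-delimited matrix; invalid pairs written as NA."""
    scale = 100.0 if percent else 1.0
    with open(path, "w") as fh:
        fh.write("\t".join(("",) + m.ids) + "\n")
        for i, sid in enumerate(m.ids):
            cells = [
                f"{m.values[i, j] * scale:.4f}" if m.valid[i, j] else "NA"
                for j in range(len(m.ids))
            ]
            fh.write("\t".join([sid] + cells) + "\n")


def write_combined_matrix(lower: DistanceMatrix, upper: DistanceMatrix, path, percent: bool = True) -> None:
    """Combined dialect: one model below the diagonal, the other above."""
    if lower.ids != upper.ids:
        raise DistanceError("combined matrix requires identical id order")
    scale = 100.0 if percent else 1.0
    with open(path, "w") as fh:
        fh.write(f"# lower triangle: {lower.model}; upper triangle: {upper.model}\n")
        fh.write("\t".join(("",) + lower.ids) + "\n")
        for i, sid in enumerate(lower.ids):
            cells = []
            for j in range(len(lower.ids)):
                src = lower if j < i else upper
                if i == j:
                    cells.append("0.0000")
                else:
                    cells.append(f"{src.values[i, j] * scale:.4f}" if src.valid[i, j] else "NA")
            fh.write("\t".join([sid] + cells) + "\n")
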