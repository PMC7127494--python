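"""Alignment-column census: conserved, parsimony-informative and singleton sites.

Only unambiguous bases (A/C/G/T) count as character states; gaps and IUPAC
ambiguity codes contribute nothing to a column.  A column with fewer than two
unambiguous bases is excluded.  A column is variable when at least two
distinct bases occur; parsimony-informative when at least two distinct bases
each occur in at least two sequences; singleton when variable but not
informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import AlignedDataset
from .distances import encode_alignment, _INVALID

CONSERVED = "conserved"
INFORMATIVE = "informative"
SINGLETON = "singleton"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class SiteCensus:
    columns: int
    variable: int
    parsimony_informative: int
    singleton: int
    per_column_class: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.variable == self.parsimony_informative + self.singleton
        assert len(self.per_column_class) == self.columns


def classify_sites(ds: AlignedDataset) -> SiteCensus:
    enc = encode_alignment(ds)
    classes = []
    informative = singleton = 0
    for col in enc.T:
        bases = col[col != _INVALID]
        if bases.size < 2:
            classes.append(EXCLUDED)
            continue
        counts = np.bincount(bases, minlength=4)
        present = int((counts > 0).sum())
        if present < 2:
            classes.append(CONSERVED)
        elif int((counts >= 2).sum()) >= 2:
            classes.append(INFORMATIVE)
            informative += 1
        else:
            classes.append(SINGLETON)
            singleton += 1
    return SiteCensus(
        columns=ds.columns,
        variable=informative + singleton,
        parsimony_informative=informative,
        singleton=singleton,
        per_column_class=tuple(classes),
    )


def write_census(census: SiteCensus, marker: str, path) -> None:
    """Study-table style report plus a BED-like per-class track."""
    with open(path, "w") as fh:
        fh.write("marker\tcolumns\tvariable\tparsimony_informative\tsingleton\n")
        fh.write(
            f"{marker}\t{census.columns}\t{census.variable}\t"
            f"{census.parsimony_informative}\t{census.singleton}\n"
        )
        fh.write("\n# per-column classes (0-based half-open runs)\n")
        fh.write("start\tend\tclass\n")
        start = 0
        for i in range(1, census.columns + 1):
            if i == census.columns or census.per_column_class[i] != census.per_column_class[start]:
                fh.write(f"{start}\t{i}\t{census.per_column_class[start]}\n")
                start = i
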