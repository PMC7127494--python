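#!/usr/bin/env python
"""Pairwise distances and site census for each marker and the concatenation.

Reads the datasets from 01, computes K2P and p-distance matrices (combined
lower/upper-triangle dialect, 300 bp minimum overlap), builds the 1084-column
COI+16S supermatrix, and classifies alignment columns into conserved,
parsimony-informative and singleton sites.
"""

from pathlib import Path

from barcodegap.dataio import concatenate, read_aligned_fasta, write_aligned_fasta
from barcodegap.distances import distance_matrix, write_combined_matrix
from barcodegap.sites import classify_sites, write_census

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent


def main() -> None:
    coi = read_aligned_fasta(DATA / "coi.fasta", DATA / "coi_metadata.tsv", "COI")
    ssu = read_aligned_fasta(DATA / "16s.fasta", DATA / "16s_metadata.tsv", "16S")
    merged, _ = concatenate([coi, ssu])
    write_aligned_fasta(merged, DATA / "concat.fasta")
    for ds, tag in ((coi, "coi"), (ssu, "16s"), (merged, "concat")):
        k2p = distance_matrix(ds, "k2p")
        p = distance_matrix(ds, "p_distance")
        write_combined_matrix(k2p, p, OUT / f"distances_{tag}.tsv")
        census = classify_sites(ds)
        write_census(census, ds.marker, OUT / f"census_{tag}.tsv")
        print(
            f"{ds.marker}: {census.columns} columns, "
            f"{census.parsimony_informative} parsimony-informative, "
            f"{census.singleton} singleton"
        )


if __name__ == "__main__":
    main()
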