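# barcodegap

Evaluation toolkit for DNA-barcoding performance of two cryptic species, built
around the workflow used to compare the mitochondrial COI and 16S rDNA markers
of the invasive apple snails *Pomacea canaliculata* and *P. maculata*: can a
short mitochondrial fragment reliably separate two morphologically confusable
species, and which marker does it better?

Given pre-aligned sequences (per marker, or concatenated into a supermatrix)
with specimen metadata, the package computes:

- **Pairwise distances** — uncorrected p-distance and the Kimura two-parameter
  distance *d* = −½ ln[(1 − 2P − Q)·√(1 − 2Q)], where P and Q are the
  transition (A↔G, C↔T) and transversion mismatch proportions. Comparisons use
  pairwise deletion (gap/ambiguity columns dropped per pair) and a minimum
  unambiguous overlap of 300 sites; saturated pairs are flagged invalid.
- **Barcoding-gap assessment** under two criteria: the *min-max gap*
  (lowest interspecific minus highest intraspecific distance, with and without
  excluding the 5% largest intra / 5% smallest inter values) and the *10-fold
  rule* (pooled mean interspecific over pooled mean intraspecific distance ≥ 10).
- **Similarity-based identification** in the TaxonDNA style: *best match*,
  *best close match* and *all species barcode*, using the distance below which
  95% of all intraspecific distances fall as the threshold.
- **Site census** — conserved, parsimony-informative and singleton columns.
- **Marker concatenation** (e.g. 612 + 472 → 1084 columns) with exact
  per-marker coordinate maps.
- **Tree-based assignment** — species assignment of query leaves by membership
  in species-pure reference clades on externally inferred phylogenies, and
  detection of cross-marker incongruence (conspecific by one marker, allospecific
  by the other — a hybridization/heteroplasmy signature).
- **A K2P sequence simulator** generating two-species-plus-outgroup datasets
  with analytically exact expected divergences, so the whole pipeline is
  testable without any sequence download.

## Worked example

```bash
python analysis/01_simulate_datasets.py --seed 1
python analysis/02_distances_and_census.py
python analysis/03_barcoding_gap.py
python analysis/04_identification.py
python analysis/05_tree_congruence.py
```

The third step prints (seed 1):

```
COI: min-max gap 5.94% (gap), trimmed 7.18%, fold ratio 9.6 (fails 10-fold)
16S: min-max gap 1.08% (gap), trimmed 1.29%, fold ratio 10.5 (passes 10-fold)
COI+16S: min-max gap 3.82% (gap), trimmed 4.59%, fold ratio 9.5 (fails 10-fold)
```

i.e. on one synthetic replicate of the study structure, both markers show a
positive barcoding gap (lowest between-species distance exceeds the highest
within-species distance, so the min-max criterion delineates the species), but
only the less variable 16S-like marker clears the stricter 10-fold mean-ratio
bar — the COI-like marker separates the species by a wide absolute margin
(~6 percentage points) yet its substantial within-species variation caps the
mean ratio near 9. The identification step then reports 100% correct
assignments for all three similarity criteria on both markers, and the tree
step flags exactly one specimen (GC7) whose two markers place it in different
species clades.

The same stages are exposed as a CLI (`barcodegap distances|census|gap|
identify|concat|monophyly|simulate|all`) and as plain library functions
(`barcodegap.distance_matrix`, `barcodegap.gap_report`, ...).

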