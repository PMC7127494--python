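# Real study data (not redistributed)

The full-study reproduction test (`tests/test_acceptance.py::test_real_data_reproduction`)
and any real-data run of the pipeline expect the following files in this
directory.  The library performs no network I/O, so you must fetch and align
the sequences yourself (e.g. with `efetch` and your preferred aligner), then
place here:

- `coi.fasta` — aligned COI sequences, 612 columns: the 40 study specimens
  (GenBank MN623417–MN623440 plus MG230743–MG230792 as applicable) and the
  public reference barcodes of *Pomacea canaliculata*, *P. maculata*,
  *P. lineata*, *P. paludosa* and *P. scalaris* (e.g. KY081757, FJ946820,
  EU528506, FJ710316).
- `16s.fasta` — aligned 16S rDNA sequences, 472 columns (specimens
  MN623441–MN623480 plus references, e.g. FJ710228, FJ710240, FJ710241).
- `metadata.tsv` — tab-delimited with header
  `specimen_id<TAB>species<TAB>role[<TAB>locality][<TAB>accession_COI][<TAB>accession_16S]`;
  `role` is `query` for the study specimens and `reference` for the GenBank
  barcodes.  FASTA ids must match `specimen_id` (the specimen id of the
  incongruent individual is `GC7`).
- optional `coi.nwk` / `16s.nwk` — externally inferred phylogenies over the
  same ids, used for the clade-assignment and congruence stage.

Reference sequences shorter than the specimen alignment should be fitted with
leading/trailing gap padding.
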