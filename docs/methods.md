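# Methods

## Distance model

Two aligned sequences are compared under **pairwise deletion**: a column
contributes only when both sequences carry an unambiguous base (A/C/G/T).
Gaps and all IUPAC ambiguity codes are excluded outright rather than matched
fractionally — the simplest reproducible reading of the common
distance-software convention, and the one documented here as a design choice
(ambiguity handling is rarely stated precisely by analysis programs). Of the
compared sites, transitions (A↔G, C↔T) and transversions give the
proportions P and Q.

- p-distance: (transitions + transversions) / overlap.
- Kimura two-parameter distance: d = −½ ln[(1 − 2P − Q)·√(1 − 2Q)],
  which corrects for multiple hits while distinguishing the two substitution
  classes; d ≥ p always, with equality only at zero.

A pair is **invalid** when its unambiguous overlap is below `min_overlap`
(default 300 sites — the overlap filter is applied to the quantity the
distance is actually computed from, not to raw ungapped length) or when the
logarithm argument is non-positive (saturation). Invalid pairs carry NaN and
are skipped by every downstream pool; saturation is never clamped to a
ceiling, which would distort gap statistics. Distances are fractions
internally; reports print percent.

## Barcoding-gap criteria

Valid distances among the **focal species** (default: the two species under
study; congeners/outgroup excluded, both scopes runnable) are pooled into
per-species intraspecific and pooled interspecific multisets.

1. **Min-max criterion**: gap = min(inter) − max(intra); positive means the
   species are delineated. The trimmed variant first removes
   floor(0.05·n) largest intraspecific and floor(0.05·m) smallest
   interspecific values (never more than 5% per tail); the trimmed gap is
   always ≥ the full gap. Both are reported, since published gap figures do
   not always state which variant they print.
2. **10-fold criterion**: pooled mean interspecific over pooled mean
   intraspecific distance. The pooled (not per-species-averaged) mean is used
   because it is the only reading that reproduces the published arithmetic
   (2.4/0.2 = 12 for the 16S-like structure; 11.2/1.2 ≈ 9 for COI-like).
   The boundary is inclusive (ratio = 10 passes); a zero intraspecific mean
   yields an infinite ratio and a pass. Scaling all distances leaves the
   ratio unchanged and scales the gaps linearly.

## Identification criteria

Every sequence — study specimens and reference barcodes alike — serves as a
query against all others with self-exclusion (configurable to
queries-vs-references only). This all-as-query mode is the default because it
is the only mode in which reference sequences themselves can fail, as reported
identification studies show. The threshold is the smallest pooled
intraspecific distance t with at least 95% of intraspecific distances ≤ t.

- **best match**: species of the nearest sequence(s); exact ties pool species
  and more than one species at the minimum is *ambiguous* (never resolved by
  input order); right species alone → *correct*, wrong species alone →
  *incorrect*.
- **best close match**: as best match, but a best distance above the
  threshold is *no match*.
- **all species barcode**: the species set of every sequence within the
  threshold; exactly the true species → *correct*; true species plus others,
  or several species → *ambiguous*; non-empty without the true species →
  *incorrect*; empty → *no match*.

Threshold comparisons are inclusive by default ("below the threshold" read so
that the defining 95th-percentile value itself passes); a strict mode is
provided. Pairs invalid in the distance matrix are invisible to
identification.

## Site census

Per column, only unambiguous bases are states. Columns with fewer than two
unambiguous bases are excluded; a column is variable with ≥ 2 distinct bases,
parsimony-informative when ≥ 2 distinct bases each occur in ≥ 2 sequences,
and singleton when variable but not informative. Counts are additive across
concatenation segments.

## Tree-based assignment

Phylogeny inference is consumed, not performed. Trees arrive as Newick with
optional support labels; the outgroup roots the tree and is pruned before any
ingroup test, and is never assigned. A query leaf takes the species of the
smallest clade containing it together with ≥ 1 reference, provided all
references in that clade are conspecific and the species' references are
mutually monophyletic; otherwise it stays unassigned. Incongruence between
two markers is the set of specimens assigned different species by each,
excluding unassigned ones. Support values are reported with assignments but
do not gate them — published accounts describe clade support qualitatively,
so no numeric support threshold is imposed by default.

## Synthetic-data generator

The generator emulates the study structure: two focal species (20 specimens
each by default), a congeneric outgroup pair, 612-column COI-like and
472-column 16S-like alignments. It evolves sequences on a **star phylogeny**:
a uniform-random root, species ancestors at branch lengths solving the star
equations A(i,j) = D_i + D_j (with A the interspecific target minus half of
each intraspecific target; infeasible combinations raise a configuration
error), and every individual at half its species' intraspecific target from
its ancestor. Each branch applies the exact closed-form K2P transition
probabilities per site — P(b) = ¼ − ½e^(−2(α+β)b) + ¼e^(−4βb),
Q(b) = ½ − ½e^(−4βb) with α/β = κ and α + 2β = 1 — so expected pairwise
distances are analytic (the inverse of the distance formula; round-trips are
exact to 1e−12) rather than Monte-Carlo approximations, and the calibration
tests can be sharp.

Parameters and defaults:

- `kappa` (transition/transversion rate ratio) = 2.0, a standard animal-mtDNA
  value; at κ = 1 the model degenerates to equal rates with Q = 2P.
- COI-like: intraspecific K2P means 2.4% / 0.0% (single haplotype),
  interspecific 11.2%, outgroup at 13%.
- 16S-like: intraspecific 0.3% / 0.1%, interspecific 2.4% (pooled mean ratio
  12), outgroup at 5%.
- `missing_data_rate` (per-site gap probability, default 0): gaps model
  missingness only; there is no indel process.
- A single integer seed drives one pseudo-random stream; identical seeds give
  byte-identical FASTA.

What the generator does *not* emulate: within-species genealogy (all
individuals are equidistant from their ancestor, so intraspecific distances
concentrate near their mean instead of spanning 0% to the maximum as real
haplotype structure does), rate variation across sites, base-composition
bias, alignment error, and the uneven lengths/padding of public reference
sequences. Consequently the synthetic pipeline demonstrates correctness of
the statistics and the expected qualitative contrasts (wide absolute COI gap
vs. ~9-fold ratio; narrow 16S gap vs. ~12-fold ratio; 100% identification at
these divergences); it does not reproduce effects that depend on real
haplotype sharing, such as minimum intraspecific distances of exactly zero
across species or threshold failures of particular reference sequences.

A note on sampling noise: in a single 16S-like replicate the realized mean
interspecific distance is dominated by the Poisson draw of substitutions on
the two shared ancestral branches (~10 expected events over 472 sites), so
per-replicate fold ratios scatter widely (roughly 8–16); calibration is
therefore assessed on ratios of means across replicates, which converge to 12.

## Numerical and policy choices

- Coordinates are 0-based half-open internally; reports print percent to the
  precision stated in each writer.
- Concatenation is strict by default (every specimen present for every
  marker); an opt-in pad-with-gaps mode exists for mixed availability.
- `?` is normalized to `-` and lowercase to uppercase on read; FASTA id is
  the first whitespace-delimited header token; species/role metadata lives in
  a separate tab-delimited table because wild FASTA headers are inconsistent.
- Problem sizes in tests and the acceptance script (replicate counts of
  25–100, 4–20 individuals per species) were chosen so the whole suite runs
  in well under a minute while keeping Monte-Carlo standard errors a few
  percent of the quantities checked.

## Known limitations

- No Gamma or other substitution models; no distance bootstrap.
- No automatic species delimitation (ABGD/ASAP/GMYC) beyond the two criteria.
- Tree stage has no support-value gate and performs no topology tests.
- The star-phylogeny simplification above.
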