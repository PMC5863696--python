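# Methods

`synortho` implements a collinearity-guided functional-annotation pipeline
for plant comparative genomics: conserved multiple-alignment anchors (MAAs)
are extracted from a multi-genome alignment, chained into collinear segments
at several phylogenetic depths, used to infer orthologous protein-coding
gene pairs with a composite support score, and finally used to transfer
ontology terms from annotated species onto a reference genome.  Annotation
sets are compared with structure-free and structure-based similarity indices
and validated against gene co-expression.  This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Markers and anchors

Two marker types drive collinearity detection:

* **MAAs** — alignment blocks conserved across a required species set
  (normally all species of the alignment), projected onto the reference
  genome.  One block yields one anchor; overlapping projections are not
  merged, so genome coverage is reported on the interval union (overlaps
  counted once).  Whether overlapping anchors should instead be merged is
  not decidable from first principles; union semantics is our choice and is
  confined to `marker_stats`.
* **Protein-coding genes** — gene models reduced to per-chromosome rank
  orders.

Marker-set descriptive statistics follow standard practice: length
distribution, union coverage, per-chromosome uniformity (one-sample KS test
of marker midpoints against the uniform distribution; chromosomes with fewer
than 8 markers are skipped), GC enrichment (two-sided Mann–Whitney rank-sum
of per-anchor GC against length-matched random windows — length matching
removes the length–GC confound, and the rank-sum test is distribution-free),
and per-base feature composition with the precedence CDS > UTR > ncRNA >
intron > intergenic, where intergenic stretches longer than 30 kbp are
classed as gene desert.

## Collinear-segment detection

A collinear segment between two genomes is a chain of homologous marker
pairs whose ranks are strictly monotone in both genomes (increasing, or
decreasing on one side for an inversion), with at most `gap_size`
intervening non-homologous markers between consecutive anchor points,
at least `anchor_points` anchors, and a significance `p <= prob_cutoff`.
Defaults follow the two marker regimes: `anchor_points = 3`,
`gap_size = 30` for MAAs and `10` for genes, `prob_cutoff = 0.01`.

**Chaining.**  Candidate pairs form a sparse DAG with an edge wherever two
pairs can be consecutive anchors (both rank gaps within `gap_size`,
orientation consistent).  Because edge validity is a rank-window constraint,
any pair that fits strictly between the two endpoints of an edge on both
genomes is itself edge-compatible with both endpoints.  Two consequences
follow, and both are load-bearing:

1. A chain is *structurally* subset-maximal exactly when it starts at a
   node with no predecessor, ends at a node with no successor, and uses only
   irreducible edges (no single node can be inserted between two consecutive
   anchors).  Root-to-leaf paths of the transitively reduced DAG therefore
   enumerate the structurally maximal chains without enumerating every chain
   (which is exponential on dense instances).
2. A subset-maximal *significant* chain is always a contiguous window of
   some structurally maximal chain: an insertable interior node always
   improves significance, so a maximal significant chain has none.

The detector exploits (2): each structurally maximal chain is scanned for
its maximal significant contiguous windows, and a final subset-maximality
pass across chains removes windows contained in larger emitted segments.
The output is exactly the set of subset-maximal significant chains; the test
suite verifies this against an independent exhaustive enumerator on random
instances.  The refinement step matters in practice: a genuinely collinear
core surrounded by incidental background homology would otherwise be
absorbed into a meandering chain that fails the significance test as a
whole.

**Significance.**  A chain of `k` anchors spanning `span_a x span_b` markers
is scored by the binomial tail `P(X >= k)` with `X ~ Bin(span_a * span_b,
rho)`, where `rho` is the background pair density of the chromosome pair
(candidate pairs over marker-count product), Bonferroni-scaled by the number
of candidate chains tested and capped at 1.  The multiple-testing factor
counts the hypotheses the detector actually examines (one per structurally
maximal candidate chain); scaling by the number of possible window positions
instead would punish short chains quadratically and make legitimate 3-anchor
segments undetectable at any realistic density.  Known limitation of the
count-based null: a map in which essentially *every* marker participates in
one saturated chain (observed count equals its own expectation) is reported
as non-significant; the model tests local enrichment, not global orderliness.

**Levels.**  With all segments anchored on a reference genome and a species
order by divergence (reference first, divergence index d = 2, 3, ...), each
pairwise segment is labelled `2way-d`.  n-way regions are maximal reference
intervals simultaneously covered by segments with every one of the first
n−1 partner species; regions are reported at the largest n they satisfy,
computed by coordinate-compressed per-base coverage (the at-least-n region
sets are nested by construction).  Whether an n-way region may be stitched
from several overlapping segments per species is an open representational
choice; we use per-base coverage, which allows it.

## Ortholog inference and OPSS

A cross-species gene pair is an orthologous protein-coding gene pair (OPP)
when (i) a similarity hit at E ≤ 1e-5 joins the genes and (ii) at least 50%
of each gene's length lies inside the two sides of one MAA-based collinear
segment (the 50% condition is read conjunctively — both genes must reach
it).  Optional evidence: (iii) bidirectional best hit (best = max bitscore,
ties broken by smaller e-value then lexicographic id), (iv) condition (ii)
against gene-based segments.  The composite score is

    OPSS = M + 0.5 · P + B

with M the maximum collinearity degree over supporting MAA-based segments
(the deepest n-way level the segment participates in, floor 2 for purely
pairwise support), P the analogue over gene-based segments (0 when absent),
and B = 2 for BBH pairs, else 0.  Maximum rather than sum keeps the score
within the interpretable range (a pair supported only by a pairwise MAA
segment scores exactly 2); one-to-many and many-to-many pairs are allowed
when each passes the conditions.  Anchor pairs shared by overlapping
segments can be assigned to a single owner (`assign_unique_pairs`) for
reporting, but scoring never double-counts because components are maxima.

## Annotation transfer and comparison

A target gene inherits the union of the terms of all its orthologs in
annotated source species; provenance records each contributing ortholog and
its OPSS.  Terms associated with fewer than 5 or more than 300 target genes
are then removed (counted in the target annotation, after transfer).  No
true-path propagation to ancestor terms is applied before counting; the
ontology hierarchy enters only through the semantic similarity index.  The
procedure is ontology-agnostic (GO and PO tables run identically).

Annotation sets are triplets (P, G, GO) — deduplicated gene–term pairs and
their projections.  Two sets are compared with (a) Jaccard on pairs,
(b) Jaccard on gene sets, and (c) the mean over genes annotated by both
results of the Wang semantic similarity between their term sets, with
best-match averaging and the canonical contribution factors is_a = 0.8,
part_of = 0.6.  Genes annotated by only one result are excluded from (c) by
default (union scoring, counting them as 0, is available).  Both choices
follow the standard use of Wang similarity; S-values are propagated upward
by taking the maximum attenuated path product, and the implementation is
tested against explicit path enumeration.

## Co-expression validation

For a term with gene set U present in the FPKM matrix, observed scores are
Pearson correlations over all within-U pairs (zero-variance genes excluded;
raw FPKM by default, log2(FPKM+1) optional).  Each repeat draws random gene
pairs without replacement and compares the two correlation samples with a
one-sided two-sample KS test (alternative: observed stochastically
greater); the mean p over 100 repeats is the term's final p, and a term is
called significant at alpha = 0.001.

The null sample per repeat is **10x** the observed pair count (capped by the
number of available pairs).  This is deliberate: because the final p is a
*mean* over repeats, per-repeat sampling noise on the null side is averaged
out, and the final p approximates the p-value of the observed sample against
the null population.  With equal-size null samples that averaging contracts
the null tail — the measured false-positive rate at alpha = 0.05 drops to
~0.2% — whereas the 10x null restores the nominal 5%.  The acceptance suite
measures both calibration (5% ± 3% over 400 null terms) and power (a planted
8-gene module with pairwise r ≈ 0.9 over 10 tissues is detected at
alpha = 0.001 in ≥ 95% of seeds).

## The synthetic world

The generator emulates every input of the pipeline with known truth.  An
ancestral genome of ordered gene families carries planted collinear blocks
(runs of consecutive families) that are copied into each partner species in
phylogenetic order; divergence is ordinal — per-gene dropout and
inversion/translocation probabilities grow with the species' divergence
index — mimicking the alignability decay seen between real genomes without
simulating sequences.  Species-specific filler genes separate blocks by more
markers than any reasonable `gap_size`, so planted chains cannot bridge.

Defaults (chosen once as the study conditions of the package):

| parameter | default | meaning |
|---|---|---|
| n_species | 5 | reference + 4 partners |
| genes_per_genome | 200 | markers per genome |
| n_planted_blocks | 7 | collinear blocks |
| block_size_range | (5, 12) | genes per block |
| inter_block_gap | 15 | filler genes between blocks |
| maa_per_block_range | (3, 8) | conserved anchors per block |
| maa_conserved_fraction | 0.8 | blocks whose anchors exist in all species |
| background_maas_per_gap | 125 | scrambled conserved anchors per inter-block region |
| noise_marker_rate | 0.1 | spurious markers inside blocks |
| rearrangement_rate | 0.1 | inversion/translocation intensity |
| ortholog_dropout_rate | 0.05 | per-gene loss, scaled by divergence |
| decoy_rate | 0.1 | near-tandem paralog hits at borderline E-value |
| n_tissues / noise_sd / latent_factor_sd | 10 / 0.3 / 1.0 | expression model (planted modules at r ≈ 0.9) |

Two world-model features deserve justification.  First, the **background
MAAs**: real multi-genome alignments yield conserved anchors throughout the
genome (about six per gene in cucumber-scale data), most of which are not in
marker-order-collinear context at any given species pair.  These scrambled
background anchors set the background density against which chain
significance is judged; a world without them has no null — every anchor is
signal — and the count-based significance model degenerates.  Their count
(125 per inter-block region, ~5 anchors per gene slot) reproduces that
marker-to-gene ratio and keeps the chaining DAG subcritical at
`gap_size = 30`.  They are confined to inter-block regions in every species:
a genomic region is either collinear (a planted block) or rearranged (the
background sea), never both.  Second, **decoy paralogs** pair a reference
gene with a nearby (within three families) non-orthologous gene at
borderline E-values and sub-ortholog bitscores; they pass the similarity
condition, often sit inside the same collinear segment, and are separated
from true orthologs by the BBH component of OPSS — exactly the failure mode
the composite score exists to down-weight.

What the generator does **not** emulate: sequence evolution (substitutions,
indels), whole-genome duplication, tandem arrays longer than the decoy
window, multi-chromosome genomes, expression compositionality or library-
size effects.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on real
genomes.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere; conversions only at file
  boundaries (MAF strand-relative rows are normalised to forward-strand
  intervals with the strand recorded; GFF3 is converted from 1-based
  inclusive).
* Tie-breaks: equally long chains prefer lower p, then smaller reference
  start; BBH ties prefer smaller e-value, then lexicographic id; detector
  output is sorted by reference region then partner region, making runs
  deterministic.
* Degenerate inputs: empty pair sets yield empty segment lists; empty
  anchor sets are an error for statistics; terms with fewer than two usable
  genes are an error naming the term; chromosomes with too few markers are
  skipped with a warning; both-empty sets have Jaccard 1 by convention.
* All randomness (background windows, null pair draws, world generation)
  flows through caller-supplied seeds; the orchestrator splits one root seed
  per stage, and re-running a pipeline with the same config and seed is
  checksum-identical.
* Problem sizes used by the test and acceptance suites (five-species
  200-gene worlds, 40-marker oracle instances, 400-term calibration runs)
  are chosen so the full suite exercises every statistical claim at
  desk scale in minutes.

## Known limitations

* The chaining significance model is approximate (binomial count null with
  a hypothesis-count Bonferroni factor), documented as such rather than as a
  clone of any existing detector's internal statistics; cloud-based or
  permutation nulls would be the next refinement.
* Condition (i) uses the E-value threshold only; no coverage or identity
  filter is applied to hits.
* Gene identifiers are treated as opaque strings; transcript-isoform
  suffixes are not collapsed.
* The n-way classifier builds profiles by reference-region intersection; it
  does not re-align multiplicon profiles.
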