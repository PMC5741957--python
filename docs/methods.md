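# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and strand conventions

All internal coordinates are 1-based, fully closed (the GFF3 convention);
BED input is converted at the reader boundary. A single shared base counts
as overlap everywhere. Strand `"."` marks unstranded evidence and is
compatible with either strand in every strand-match test, because EST-derived
alignments frequently carry no orientation; when unstranded evidence updates
a gene, the gene's strand orients the 5′/3′ assignment. All seq_ids
(chromosomes and scaffolds) are treated uniformly.

## Overlap classification

Classification is span-level, not exon-level: the taxonomy is defined by how
the transcript's 5′ and 3′ edges relate to the gene's edges (beyond the
edge, coinciding, or inside), with 5′/3′ read in the gene's strand
orientation — on the minus strand the 5′ edge is the higher genomic
coordinate. The 3 × 3 edge-relation table yields nine mutually exclusive,
jointly exhaustive categories for overlapping pairs (verified by exhaustive
enumeration on small grids); alignments touching ≥ 2 genes are merge
evidence and alignments touching none are intergenic. Exon-aware refinement
happens later, in the update step. Two symmetries hold and are tested:
reflecting all coordinates on the *same* strand swaps the 5′/3′-directional
categories, while reflecting *and* flipping the strand maps 5′ onto 5′ and
fixes every category.

Drought labelling: a gene is drought-responsive iff at least one overlapping
EST cluster is drought-only or mixed. Mixed clusters confer the label by
default because mixed-content clusters are counted among the mapped
drought-responsive clusters; `mixed_clusters_confer_drought=False` restricts
to drought-only clusters.

## HSP chaining

The 2000 bp rule is applied to the *total chain span* (not the inter-HSP
gap): chaining is greedy left-to-right by target start within each
(seq_id, strand) group, closing a chain as soon as the next HSP would push
the span past the limit. This is the simplest deterministic rule satisfying
the span constraint. Identity ("at least 80 %") and validity ("95 % / 90 %")
thresholds are inclusive; filter thresholds later stated as "greater than"
are exclusive — the inclusive/exclusive choice mirrors the wording each
threshold was stated with. Coverage is computed on the query and capped at
100 %.

## Annotation update

Updates are driven by evidence sequence not covered by any existing exon:
segments inside the original gene body become new exons; segments beyond the
5′/3′ edge become UTR exons (at most 2 per end, nearest first) together with
a single span-extension record. An overlap gate requires the evidence and
gene spans to overlap over ≥ 80 % of the *shorter* span before any update is
applied, so a sliver of overlap cannot rewrite a gene while clean extensions
and containments (whose overlap is the whole shorter feature) pass. Applying
the same evidence twice is a no-op, and the comparison runs in two rounds
with the second required to be a fixed point — the tests assert zero
second-round records.

Merged genes join their identifiers with `_` in genomic order, take the
envelope span of the inputs plus the evidence, and carry all input
transcripts plus one evidence-derived transcript.

### Splice events

Events are computed from intron chains (gaps between consecutive exons) and
oriented to the first argument `a` against the reference `b`:

- `RETAINED_INTRON(a,b)`: `a` expresses sequence within an intron of `b` —
  either an exon of `a` spans the whole intron, or an internal exon of `a`
  lies inside it (a cassette exon `b` splices out).
- `SKIPPED_EXON(a,b)`: the exact mirror (`b` expresses sequence inside an
  intron of `a`), so swapping the arguments swaps the two types — a duality
  the property tests assert on random exon chains.
- `ALT_ACCEPTOR` / `ALT_DONOR`: overlapping intron pairs sharing the donor
  (acceptor) splice site but not the other, with donor/acceptor roles
  assigned per strand.
- `ALT_EXON`: overlapping exon pairs sharing no edge coordinate.
- `ENDS_IN_INTRON` / `STARTS_IN_INTRON`: a terminal exon of `a` whose
  3′ (5′) end falls inside an intron of `b`.

Identical (event, feature-pair) combinations are reported once. Splice-site
dinucleotides are not validated (no sequence is in scope).

## Novel-gene screening

Five criteria; the first two are mandatory, the rest form a disjunction:
`pass = c1 ∧ c2 ∧ (c3 ∨ c4 ∨ c5)` with c1 = no shared base with any
existing gene on either strand, c2 = span length > 200 bp, c3 = predictor
score ≥ 0.5, c4 = homology evidence with support > 50 % (ab initio
predictions fail c4), c5 = ≥ 100 bp of intergenic distance to the nearest
neighbour on each side. The neighbour-orientation aspect of c5 is
operationalised as the same gap threshold for same- and opposite-strand
neighbours, since no separate values are available. A `strict_filter` mode
requires all five. Intergenic distance counts the bases strictly between
spans; a missing neighbour is unbounded and satisfies c5. Possible processed
pseudogenes (single-exon models with no UTR) are only flagged in a report
column, never called.

Completeness: both UTRs → complete; one UTR → semi-complete on that side; no
UTR with start and stop codons → partial. Exon/intron accounting uses the
representative (first) transcript, so per group introns = exons − genes, an
identity the tests check on every synthetic gene set.

## Expression statistics

- **Grouping.** "Treatment" compares drought vs control pooling tissues;
  "tissue" compares the two tissues within the drought arm.
- **Fold change** uses a pseudocount: 1 for integer count matrices, 0.01 for
  abundance-scale data. Calls: up at ≥ 2-fold, down at ≤ 0.5-fold.
- **t-test**: pooled-variance unpaired t with df = n1 + n2 − 2; zero-variance
  genes get p = 1 when the means agree (p = 0 otherwise).
- **Rank product**: ranks are computed per replicate comparison, pairing
  disjoint replicates (k = min(n1, n2)). Pairing disjoint replicates keeps a
  gene's ranks independent across comparisons under the null, which is what
  the permutation null assumes; using all n1 × n2 crossed comparisons shares
  replicates between comparisons, correlates the ranks, and empirically
  inflates the type-I error several-fold. The null is enumerated exactly
  (all n^k rank tuples) when n^k ≤ 2·10^6 and otherwise estimated from
  10 000 Monte-Carlo rank tuples with +1 smoothing. Two-sided significance
  uses 2·min(p_up, p_down), capped at 1.
- **Fisher's exact test** builds, per gene, the 2 × 2 table of the gene's
  pooled counts vs all remaining counts across the two groups (the table
  construction is a package choice; a per-sample-pair variant would be a
  straightforward extension). Non-integer matrices are rejected; the
  pipeline rounds abundance data before this test.
- **FDR**: Benjamini–Hochberg step-up per test. A gene is significant for a
  test when its raw p beats the per-test threshold (0.01 for t-test and rank
  product, 0.05 for Fisher) *and* its q-value beats 0.05; the consensus is
  the intersection across tests.

Calibration (asserted by the acceptance tests, 5000-gene null, n = 4 per
group, lognormal noise σ = 0.25 in log2 units): both the t-test and the
rank product reject at nominal 0.01 within [0.005, 0.02], and the
rank-product p-values are KS-uniform. Under the planted design (1 % DE at
log2FC = 2, σ = 0.25) the consensus recovers ≥ 90 % of planted genes with at
most one false positive.

## Enrichment, orthologs, QTLs

Term enrichment is a two-sided Fisher's exact test per term (the sum of
table probabilities ≤ the observed table's), matching common
singular-enrichment practice; a one-sided over-representation mode is
available since sidedness is a convention. The background defaults to all
genes in the term map. Parent edges are propagated by transitive closure
(cycles are an error naming the cycle); ancestors therefore always annotate
at least as many genes as their descendants.

Ortholog screening keeps records with identity strictly above 50 % and high
confidence, all homology types admissible; a > 90 % preset serves stringent
cross-species comparisons. Shared-set accounting groups source genes by the
exact species set they hit, giving exclusive Venn regions that partition the
represented genes.

QTL co-localization is strand-blind ≥ 1 bp span overlap; partial overlap
counts. The alignment route keeps the best hit per gene (lowest e-value,
ties by bit score) passing e < 1e−10 and identity > 80 %. The e-value
ceiling defaults to 1e−10 (the general mapping cutoff); a 1e−100 preset
(`QGW_FINE_MAPPING_PRESET`) serves fine-mapped regions where the stricter
value applies. The headline co-localized share is reported to the nearest
integer, the detail field to one decimal.

## Synthetic data

Generators draw on integer grids with a 50 bp minimum feature length (so
single-base degenerate categories cannot arise unless requested), geometric
exon counts capped at 6, inter-gene gaps ≥ 150 bp, and lognormal expression
(per-gene baseline N(log2 100, 1.5²) in log2 space, replicate noise
N(0, σ²), planted genes shifted by log2FC in every drought sample). The
default study conditions are n = 4 replicates per treatment × tissue cell,
σ = 0.25, log2FC = 2 and 1–2 % planted DE — values a small crop RNA-seq
drought experiment would plausibly produce. Everything is deterministic
under a fixed seed; every generated record is traceable to a truth entry,
and each truth is exactly recoverable by its analysis stage under noiseless
settings (the closed-loop tests assert 100 % recovery).

An optional count mode replaces the lognormal output with a
negative-binomial (gamma-Poisson) draw around the same means, giving integer
matrices for exercising the exact test on counts.

What the generators do *not* emulate: sequence content (no FASTA), mapping
ambiguity and repeat-driven misalignment, library-size variation, and
correlated gene expression. Passing closed-loop tests therefore
demonstrate the correctness of the decision logic and the calibration of the
statistics under the stated noise model, not robustness to real-data
artefacts.

## Pipeline and determinism

All randomness flows from one top-level seed (stage seeds are fixed offsets
from it). Reports are byte-stable across identical runs; the manifest is the
single exception because it records wall-clock stage timings, so determinism
checks compare every output except `manifest.json`. Problem sizes in the
bundled synthetic profile (60 genes over 3 chromosomes, 8 alignments per
overlap category, 400-gene expression matrix, 5000-gene null simulations)
were chosen to make the full suite and the acceptance script complete in
seconds while keeping every rate estimate stable across seeds.

## Known limitations

- Overlap calls are span-level; a transcript overlapping only the intron of
  a gene still counts as genic evidence.
- File-based (non-synthetic) pipeline runs currently require the synthetic
  profile for everything beyond annotation parsing; the library functions
  accept real tabular inputs individually.
- The rank-product Monte-Carlo p-value floor is 1/(N+1); genes below it tie.
- Open-reading-frame re-prediction, repeat masking, live database
  annotation and visualisation are out of scope by design.
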