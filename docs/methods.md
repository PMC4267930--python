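# Methods

## Scope and model

`annoforge` covers the annotation-reconciliation layer of a comparative
RNA-seq reannotation study: it starts from predicted and reference gene
models (GFF3 + genome FASTA), protein similarity evidence, per-base read
coverage, per-gene expression, and per-gene differential-expression
p-values, and produces merged annotations, ortholog tables,
lineage-specific gene calls and cross-species bias-concordance summaries.
Read mapping, transcript assembly, gene prediction and the differential
expression test itself are deliberately upstream: the statistical
contracts here begin at their outputs (models, hits, counts, p-values),
which is what makes every downstream number reproducible from flat files.

## Reconciliation

A predicted model matches a reference model when all four conditions hold:

1. CDS intervals overlap by >= 1 bp on the same scaffold and strand;
2. reference-protein coverage >= `cds_coverage_min` (default 0.85);
3. amino-acid identity >= `aa_similarity_min` (default 0.90);
4. E-value <= `evalue_max` (default 1e-10).

Choices made where the procedure is genuinely open:

- *Strandedness.* Antisense overlap is not treated as homology evidence;
  `require_same_strand=False` restores strand-agnostic matching.
- *Isoforms.* Matching is evaluated at the gene level on each gene's
  longest-CDS transcript; transcript-level isoform reconciliation is out
  of scope.
- *Coverage side.* The 85% coverage condition is measured on the
  **reference** protein (protecting reference gene integrity — coverage of
  the shorter sequence would pass spurious fragments); `coverage_side`
  switches it.  With externally supplied hit tables this means the table's
  queries must be reference proteins.
- *Similarity vs. identity.* "Amino-acid similarity" is operationalized as
  percent identity from the alignment — the stricter and more reproducible
  reading — and is configurable.

Classification is a partition: exactly one match -> one_to_one, >= 2 ->
polycistronic, 0 -> novel.  Members of a polycistronic call must each
individually pass the thresholds, preventing incidental 1-bp overlaps from
being counted as fusion members.  Orphan rescue is inclusive at
FPKM >= `fpkm_rescue_min` (default 2.0); missing expression counts as 0.
The merge emits all predictions, rescued orphans, and — per the
dual-annotation rule — each fusion member without a one-to-one prediction
of its own, with id collisions resolved by source-prefixing.

FPKM is count * 1e9 / (length * N); `total` mode uses the summed library
count for N, `upper_quartile` uses the 75th percentile of nonzero gene
counts scaled by the gene count (its library-size equivalent), the common
upper-quartile convention.  Both are invariant to proportional scaling of
a library.

Feature support: a feature counts as supported when >=
`feature_covered_fraction_min` (0.5) of its bases reach depth >=
`feature_depth_min` (1.0); a gene is supported when >=
`feature_support_min` (0.60, inclusive) of its deduplicated features are
supported.  The 60% gene-level criterion is the load-bearing threshold;
the two per-feature knobs are pragmatic defaults with no canonical value,
hence both sit in `Config`.

## Homology evidence

Standard 12/13-column similarity tables are parsed with duplicate
(query, subject) rows collapsed to the best E-value (ties: highest
bitscore, then first occurrence).  For self-contained fixtures the package
also ships an internal pairwise aligner: Smith–Waterman-style local
alignment (Biopython's `PairwiseAligner`, BLOSUM62, affine gaps -11/-1, no
low-complexity masking) with a pseudo-E-value
`E = K * m * n * exp(-lambda * S)` using the gapped BLOSUM62 constants
lambda = 0.267, K = 0.041.  This transform is a calibration, not a claim
to exact search-tool statistics: identical 100-mers score around 1e-62,
unrelated random 100-mers around 0.1–1, so the 1e-10 cutoff separates the
two regimes by ~50 orders of magnitude.  All-by-all search seeds candidate
pairs by shared exact 4-mers (>= 3 shared) before aligning — at the study
divergence (15%/branch, ~72% pairwise identity) a true pair shares ~30 of
~120 4-mers while unrelated pairs share < 1 in expectation, so the
prefilter is lossless where alignment could succeed at all, and keeps
500-gene proteomes to a few seconds on one CPU.

## Orthology

Rank assignment sorts a query's hits by E-value (deterministic tie-break
on subject id) and groups greedily, **anchored** at each group's best hit:
a hit joins the group iff log10(e) - log10(e_best) <= `log_unit` (1.0,
inclusive).  Chained grouping (each hit compared with its predecessor) is
available as `rank_grouping="chained"` but lets unbounded E-value drift
share one rank, which is why anchoring is the default.  E-values of 0 are
floored at `evalue_floor` (1e-200) before the log.  Within-species
self-hits are dropped before ranking.

A pair (a, b) is an ortholog iff b sits at rank r in a's list and a at the
same rank r in b's; "same rank order" at any depth is accepted
(many-to-many permitted), with the `first_order` flag marking rank-1/rank-1
pairs — the headline per-species-pair counts are of genes with >= 1
first-order ortholog.  Lineage-specific genes have zero qualifying hits
against **all** outgroups; a missing outgroup table is an error, because
absence of evidence must be explicit.

## Expression layer

Benjamini–Hochberg is applied per contrast (statsmodels' `fdr_bh` behind
the module surface; an independent quadratic-time step-up implementation
serves as the test oracle).  BH is used as the standard step-up rule; the
upstream study's own FDR machinery is internal to its testing engine and
out of scope.  Significant genes with a nonzero log2 fold are biased
toward the higher tissue; a zero fold with significance is logged and left
unbiased.  Concordance restricts to *unique* first-order pairs (genes in
several first-order pairs are dropped — one gene, one ortholog) and
reports `same-bias orthologs / biased genes with a retained ortholog`.

## Synthetic data generator

One `random.Random(rng_seed)` drives everything; equal seeds give
byte-identical trees (all container iteration is sorted, so the output is
independent of hash randomization).

- *Divergence* is protein-space: each residue substitutes independently
  with the per-branch probability to a uniformly chosen different residue;
  nucleotide CDSs are deterministic back-translations (lexicographically
  first codon).  Codon-level models and indels are out of scope — the
  downstream statistics operate on protein similarity, which this
  reproduces directly.
- *Gene structure* is a fixed toy layout (60 bp UTRs, two CDS exons split
  at a codon boundary around a 60 bp intron) on two major-arm scaffolds
  plus one minor scaffold, mirroring the major-arm vs. other split at toy
  scale.  Lineage-specific genes alternate between a major arm and the
  minor scaffold.
- *Fusions* place the two member genes adjacently on the plus strand and
  emit a single predicted model whose CDS is member A minus its stop codon
  followed by member B — the fused protein is the concatenation of the
  member proteins, as a read-through ORF prediction would produce.  (Only
  the planted-fusion layout is plus-strand; strand handling everywhere
  else is general.)
- *Orphans* are reference genes omitted from the prediction set with
  planted FPKMs alternating above and below 2.0.
- *Support* is planted at gene level, all-or-none: a gene is supported
  with probability `fraction_supported_features` and then covered over its
  whole span, otherwise left uncovered.  The parameter therefore equals
  both the expected fraction of supported features and of supported genes,
  which keeps the support-summary calibration interpretable.
- *DE p-values*: null genes draw p ~ Uniform(0,1); biased genes draw
  z ~ Normal(`effect_size`, 1) and p = 1 - Phi(z), with the fold-change
  sign carrying the planted direction.  Bias is anchored on the first
  species (per-contrast fraction `fraction_de`, default 0.6 — in gonad
  vs. soma contrasts a majority of genes genuinely are differentially
  expressed); each other species' ortholog inherits the same direction
  with probability `shared_bias_probability` (default 0.6) and is
  otherwise null.  The default `effect_size` of 6 gives near-complete
  power at FDR 0.1, so planted quantities are recoverable rather than
  power-limited.

What the generator does **not** emulate: read-level noise, isoform
diversity, indels, paralog families, assembly fragmentation, correlated
expression across genes.  Passing planted-truth tests therefore
demonstrates the correctness and calibration of the analysis layer, not
robustness to those real-data failure modes.

### A note on concordance calibration

Measured concordance conditions on *detected* bias in species A, so
falsely significant null genes enter the denominator and attenuate the
estimate by roughly the false-discovery fraction, ~alpha * pi0 (their
orthologs are null and almost never show the same bias).  This follows
from the FDR contract, not from implementation.  The calibration check is
therefore run in a high-signal configuration (fraction_de = 0.9,
effect_size = 6 => power ~ 1, attenuation ~ 1%), chosen by this power
analysis so the planted sharing probability is the estimator's
expectation.  The same argument implies that a real study's measured
"roughly 60%" concordance slightly understates the true conservation of
tissue bias whenever many tested genes are null.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; GFF3/bedGraph conventions
  convert at the boundary, and the conversion is an exact bijection.
- Partial CDSs (length not divisible by 3) are flagged and translated to
  the last full codon; codons containing N translate to X.
- Empty hit lists, empty prediction sets, zero-depth coverage and missing
  expression all degrade to well-defined results (empty ranks, all-orphan
  references, unsupported genes, FPKM 0) rather than errors; structural
  inconsistencies (dangling GFF3 Parents, scaffolds absent from the
  genome, overlapping coverage intervals) raise typed errors.
- Problem sizes in tests and the acceptance script (500-gene proteomes for
  recovery, ~2000 biased genes for concordance, 1000 null replicates for
  FDR control) were chosen so each statistic's sampling error is small
  against its acceptance band while the whole suite stays fast on one CPU.

## Known limitations

- The pseudo-E-value is a calibrated monotone transform, not a
  Karlin–Altschul estimate; absolute E-values from the internal aligner
  should not be compared with search-tool output, only thresholded.
- Gene-level matching on the longest-CDS transcript can misclassify genes
  whose isoforms differ radically.
- The k-mer prefilter (and local alignment generally) cannot detect
  homology below ~30% identity for proteins of this length; orthologs
  diverged beyond that are indistinguishable from lineage-specific genes
  for any hit-based definition.
- Concordance drops ambiguous many-to-many ortholog pairs; gene families
  with recent duplications are under-represented in the comparison.
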