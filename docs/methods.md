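# Methods

`orthoflora` re-implements, as a tested library, a comparative-genomics
inference chain for identifying soybean (*Glycine max*, the "target"
species) orthologues of Arabidopsis ("reference") flowering-time genes
and characterising their copy number, expression, genomic distribution
and wild-relative variation. This note records the models, conventions
and deliberate design choices behind each stage.

## Orthologue-group unification

Two homology sources are merged: per-gene annotation links (target gene
→ closest reference gene) and a pre-computed multi-species
orthologue-group (OG) membership table with `OG5_*` identifiers.
Precedence follows the order the sources are applied in practice:
annotation links first, membership only for unlinked genes. A reference
gene with links but no membership OG receives the synthesized ID
`OG5_<locus>`; a synthesized ID colliding with a real input OG ID is an
error rather than a silent merge. Genes with neither source are kept in
an explicit *unassigned* bucket so the unmapped remainder of a genome is
auditable, and every emitted assignment carries a `source` column
(`link` / `membership` / `synthesized`) because the two sources can
genuinely disagree for a gene and the choice should be visible. All ID
matching is case-sensitive exact string comparison. Isoform selection
for upstream proteome preparation keeps the longest protein per locus,
breaking length ties by lexicographically smallest isoform ID for
determinism.

## Clade-based orthologue refinement

OG membership is coarse in a paleopolyploid: an OG often holds many
target-species paralogues of which only some descend from the flowering
reference gene. The refinement rule accepts a target gene as a
flowering orthologue when it lies in the same clade as a flowering
reference gene, *unless* some other reference gene is equally close or
closer.

Operational choices, where the verbal rule is under-determined:

* **"Same clade"** is the smallest clade containing the target leaf and
  at least one reference-species leaf. This is the minimal
  deterministic reading; it never depends on where larger clades are
  drawn. Inputs whose root is a polytomy are treated as unrooted and
  midpoint-rooted first (clades are undefined on unrooted trees);
  patristic distances are rooting-invariant, so only the clade boundary
  is affected.
* **"Closer"** is the patristic distance (branch-length sum along the
  leaf-to-leaf path), compared with an absolute tolerance (default
  `1e-9`, configurable) since branch lengths are floating point. The
  competing distance is the minimum over *all* non-flowering reference
  leaves in the tree, not only those in the clade — a conservative
  reading of "another gene".
* Missing branch lengths default to 0 with a warning, so topology-only
  consensus trees degrade to pure clade membership.
* Internal node labels (bootstrap support out of 1000 replicates) are
  parsed and reported but never used for classification: no support
  threshold is part of the rule.
* OGs with fewer than four sequences cannot have trees (four is the
  minimum for tree inference), so a small-OG shortcut applies: all
  target members are accepted when the OG's reference members are a
  non-empty subset of the flowering list, otherwise all are left
  `unresolved`.

## Transcriptional activity and expression clustering

Two dataset-specific activity rules are supported: for raw sequence
reads, a gene is active with ≥ 2 reads in at least one
tissue/developmental stage; for normalized counts, any value > 0
suffices. Calls from several datasets are OR-combined, and
flower-expression flags re-apply the same rule restricted to the
declared flower conditions (condition vocabularies are free-form labels
declared in configuration, never inferred from names). Calls are
monotone by construction: adding reads can never deactivate a gene.

Profiles are standardised per gene to Z-scores using the population
(divide-by-*n*) deviation, matching the convention of the classic
expression-clustering tools; zero-variance rows map to all-zeros rather
than NaN. Hierarchical clustering defaults to correlation distance
(d = 1 − Pearson r) with average linkage — the typical configuration of
those tools — with complete linkage and Euclidean distance as
alternatives; the chosen settings are recorded in the output so a
clustering is reproducible up to that choice. Zero-variance rows get
distance 1 to every other row (explicit, testable, no NaN propagation).
Merging is delegated to `scipy.cluster.hierarchy.linkage`, whose tie
ordering is deterministic for a fixed input; dendrogram comparisons in
the test suite therefore use cophenetic distances, which are invariant
to the order of equal-height merges. Agreement between a flat
expression clustering and the OG partition is quantified with the
adjusted Rand index (the underlying biological claim — that sequence
grouping and expression grouping disagree — is qualitative; the ARI
makes it measurable).

## Paralogue copy-number statistics

For each OG with at least one gene in both species, the statistic is
log2(n_target / n_reference). OGs with a zero count on either side are
excluded from the distribution (the ratio is undefined) and reported in
a side table. The distribution is summarised by its mean and standard
deviation — sample (n − 1) SD by default, with the estimator recorded —
and OGs are classified *paralogue-rich* when the ratio is strictly
greater than mean + k·sd, *paralogue-less* when strictly below
mean − k·sd (k defaults to 2, configurable). On the genome-wide
distribution (mean 1.03, sd 0.88 in log2), the upper fold threshold
2^(mean + 2·sd) ≈ 6.9 — about seven-fold more target copies — while the
lower is 2^(mean − 2·sd) ≈ 0.60. Note the asymmetry: the lower
threshold is *not* 0.5, even though "half or less" is the natural
verbal gloss; both numbers are reported and neither is forced to match
the other.

## Genomic distribution

Per-chromosome summaries count flagged (paralogue-rich-OG) genes as a
fraction of all genes on the chromosome; the percentage of recently
duplicated segments per chromosome is an *input* column from the genome
resource, never computed here, and correlation with the flagged-gene
fraction uses the ordinary Pearson product-moment coefficient. The
window scan tiles each chromosome with windows of configurable size
(default 1.4 Mb, the width of the empirically observed cluster) at a
configurable step (default 100 kb — the source analysis names only the
region width, so the step is a package choice). A gene belongs to a
window iff its **start** coordinate lies inside, which is unambiguous
for boundary-straddling genes and makes non-overlapping windows exactly
conserve counts. Hits are ranked by flagged count, ties by (chromosome,
start); coordinates are emitted both 1-based inclusive and BED-style
0-based half-open.

## Variant overlap

Coordinates are 1-based inclusive internally (GFF3 convention).  The
promoter is the 1 kb (configurable) strictly upstream of the gene
start, strand-aware, clamped at the chromosome boundary, and never
overlapping its own gene body. Each SNP is categorised per gene as
`CDS` → `genic_noncoding` (gene body outside every merged CDS; UTRs and
introns are not distinguished) → `promoter` → `outside`; for a given
gene these categories partition the chromosome. A SNP inside one gene's
promoter and a neighbour's body counts once for each gene
independently. The non-coding-only census counts genes whose SNPs all
avoid CDS among genes with at least one SNP, reporting count and
percentage at one decimal. SV overlap flags a gene for a deletion /
insertion / inversion whose interval intersects the gene body or
(optionally) the promoter — enabling the promoter can only add flags.
Enrichment of SV-hit genes in a gene subset uses the two-sided Fisher
exact test; the source analysis states no test, so this is an artifact
statistic and labelled as such in the output.

## Synthetic data

The generator emulates the *structure* of the real inputs (no
nucleotide or protein sequences are produced) with ground truth for
every stage. One root seed derives an independent `numpy` SeedSequence
stream per stage, so stages re-run in isolation reproduce byte-identical
outputs.

* **OG universe.** Reference counts are 1 + Poisson(1.5) (small
  integers, mean 2.5, unspecified upstream — only the ratio structure
  matters downstream); target counts are round(ref · 2^z) with
  z ~ N(mean, sd), clipped at 1, defaults mean 1.03 / sd 0.88 / 11,344
  OGs — the published genome-wide conditions. Linear-scale rounding was
  chosen over log-scale nearest-integer because its discretisation bias
  on the log2-ratio mean is an order of magnitude smaller (≈ +0.002 at
  the default parameters, versus a ±0.025 three-standard-error recovery
  band at n = 11,344). The generating z and the class it implies are
  recorded as truth; with sd = 0 the emitted integer counts can
  represent the mean exactly only when 2^mean · ref is integral, so
  truth is defined on the generating ratio.
* **Gene trees.** An explicit duplication history: pre-speciation
  duplications (1 + Poisson(0.4) subfamilies) partition the family;
  each subfamily speciates at height 1.0 into a reference clade and a
  target clade (either side may be lost), subfamilies join at
  increasing greater heights, and within-clade joins are random
  ultrametric. Branch lengths are optionally perturbed by multiplicative
  log-normal noise; the true closest reference gene(s) per target leaf
  are read off the noiseless tree. Because the noiseless tree is
  ultrametric, *all* reference genes of a subfamily are exactly
  equidistant co-orthologues of its target leaves; planted-label
  recovery is therefore evaluated with flowering sets aligned to these
  tie groups, and targets whose anchor group straddles the flowering
  set are ambiguous by construction and excluded from recovery tallies.
  Real trees are not ultrametric (rate variation does the tie-breaking);
  this is the main respect in which passing recovery tests understate
  difficulty on real data.
* **Expression.** Planted clusters share a block-structured integer
  template (high counts ~50 in a distinct condition block, baseline 2
  elsewhere, 14 conditions of which 3 are flower conditions);
  counts are gamma-Poisson (negative binomial, dispersion 0.3 by
  default), with dispersion 0 returning the templates exactly; 5% of
  genes are forced all-zero to exercise inactivity.
* **Genome and variants.** Genes (3 kb) are placed without overlap on
  50 Mb chromosomes; 60 flagged genes are condensed into a planted 1 Mb
  span, 40 more flagged genes and ~1,000 background genes are placed
  uniformly. Each gene model carries two CDS blocks framing a central
  intron, so every SNP category is realisable; SNPs are planted with
  known per-category counts and SVs with known gene overlaps.

## Problem sizes and numerical conventions

The test suite runs the distribution-recovery check at the full
11,344-OG condition (it is cheap) and the oracle suites at 100–200
random trees, 5–10-row clustering matrices, toy genomes of 3–20 genes
with tens to hundreds of variants, and 1,000-gene window-scan
chromosomes — sizes at which the brute-force oracles are exact and
instantaneous. Floats in emitted TSVs are serialised at six significant
digits so repeated runs are byte-identical; the patristic tolerance
default is 1e-9; percentage summaries round to one decimal.

## Known limitations

* The clade rule's midpoint rooting of unrooted inputs is a choice, not
  a property of the upstream tree builder; a differently rooted input
  can shift clade boundaries (never distances).
* "Closer" is branch-length based; a topological (node-count) variant
  is possible but not currently selectable per call.
* UTRs are not modelled: genic non-CDS positions are a single category.
* The generator plants no inter-gene overlap, nested genes, or
  alternative isoforms, and its trees have no horizontal structure
  (hybridisation) or rate variation; conclusions from synthetic
  recovery transfer to real data only up to those simplifications.
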