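# Methods

`mitocross` implements a systems-genetics workflow for panels of inbred
mouse strains descended from eight founder lines (Collaborative-Cross-like
panels), where mitochondria are inherited maternally and without
recombination: every strain carries the intact mt-genome of one founder,
so mitochondrial genotypes follow from pedigree alone.  The workflow has
three analyses: a trait-GWAS against mitochondrial markers, a trans-eQTL
scan of nuclear gene expression against the same markers (with rank
aggregation, gene-set enrichment, over-representation and a dual-genome
candidate overlap), and a tanglegram comparison of haplotype-level trait
clustering against founder mt-sequence clustering.

## Genotypes

A strain's allele at a marker is its maternal founder's allele, so the
genotype matrix of an `n`-strain panel has at most eight distinct rows.
Dosage codes the major allele (most frequent among the eight founders,
alphabetical tie-break) as 0; biallelic markers get 0/1, multi-allelic
markers get 0..k-1 class codes tested jointly.  Markers whose dosage
columns are identical or complementary form one *strain-distribution
pattern*; only distinct patterns are statistically independent tests, and
a mitochondrial genome typically yields very few of them.  Coordinates
are 1-based on a circular genome of configurable length (default
16,299 bp, the mouse mt reference).  Heteroplasmy is assumed absent.

## Preprocessing

Traits: per treatment arm (Ctrl / Iso), each trait is z-transformed
across animals (sample SD, n−1), residualised by OLS on sex and
experimenter (dummy-coded, intercept kept), and collapsed to unweighted
strain means.  Missing values are dropped per trait.  Whether to fit
animal-level or strain-level observations is genuinely open; strain means
put the analysis at the unit where the genotype lives and are the default
here (weighted collapse would be a one-line change in
`collapse_to_strain`).

Expression: genes are kept when at least 10 counts appear in at least 50%
of all samples (both boundaries inclusive); retained counts are
normalised to log2(CPM + 1) with library size recomputed over retained
genes; per arm, each gene is residualised on sex and library plate and
collapsed to strain means.  No TMM/size-factor or variance-stabilising
normalisation is attempted — the linear-model eQTL path only needs an
approximately homoscedastic quantity per strain.

## Association and family-wise error control

Each strain-level feature is regressed on each marker's dosage
(`y = a + b·dosage`); biallelic markers give a two-sided t test with
n−2 df, multi-allelic markers a one-way ANOVA F test.  Markers that are
monomorphic, or with any dosage class below 3 strains, are recorded as
skipped rather than silently dropped.

Because markers within a pattern are perfectly correlated, Bonferroni
over 21 markers would be badly conservative.  The family-wise error rate
(FWER) is controlled by the permutation distribution of the minimum p
value: `n_perm` standard-normal strain phenotypes are drawn (a child
stream of the seed), scanned against all distinct usable patterns, and
the FWER-level quantile (type-7) of the per-draw minimum p becomes the
study-level threshold.  One threshold serves every trait and every gene
scanned against the same genotype matrix (the threshold object carries a
fingerprint of that matrix and hit-calling verifies it).  A feature is a
hit when its minimum p is strictly below the threshold.  Both 1% and 5%
FWER levels are computed by default.  A per-feature observed-label
permutation variant (`permute_observed_threshold`) is provided for
comparison.

Known limitation, measured on synthetic nulls: the strain-level normal
null does not represent the covariance introduced when animal-level
experimenter correction interacts with within-strain correlation, making
the trait path mildly anticonservative under the default synthetic
design (true FWER ≈ 0.055 at nominal 0.05, estimated from 16,000 null
traits).  The expression path behaves the same way.  This ~10% relative
inflation is well inside the Monte-Carlo margins of the shipped
calibration checks but should be kept in mind when a threshold sits
exactly at a decision boundary.

## Enrichment

Per arm, the gene × marker t statistics are aggregated to one signed
score per gene: the median across markers for the eQTL ranking (stable
under the panel's correlated markers), or the maximum-absolute value
(sign kept, first contrast wins ties) when combining haplotype contrasts.
The ranked list feeds a classic weighted Kolmogorov–Smirnov preranked
GSEA (weight exponent 1 on |score|): the null is gene-label permutation,
NES is ES over the mean |null ES| of matching sign, p is the
matching-sign tail fraction with a +1 correction, and Benjamini–Hochberg
adjusts across sets (defaults: 1,000 permutations, set sizes 5–500 after
universe intersection).  The leading edge runs from the top of the list
to the extremum for positive ES and from the extremum to the bottom for
negative ES.

Over-representation of an annotation (e.g. MitoCarta membership) among
hits is a one-sided hypergeometric test on the tested-gene universe.
Rank distributions of an annotation's genes between arms are compared
with a two-sided Wilcoxon rank-sum test (exact enumeration when both
groups have ≤ 8 untied values, otherwise the tie- and
continuity-corrected normal approximation).  Finally, hit genes are
intersected with an external nuclear-eQTL gene list; each candidate row
carries its best model p and t, all passing marker positions, trait
labels mapped from those markers via the trait-GWAS, the external trait
labels, and MitoCarta membership, sorted by p.

## Dendrogram comparison

Haplotype-level trait matrices (mean of strain means per haplotype per
arm, traits z-scored) are clustered with euclidean distance; founder
sequences with p-distances (gap positions excluded pairwise) from a
supplied alignment.  Linkage defaults to average (UPGMA); complete and
Ward are available, all via a Lance–Williams agglomeration with a
deterministic tie-break (equal-distance merges pick the clusters holding
the lexicographically smallest labels), validated against scipy.

Two trees are compared by (i) the entanglement score of their leaf
orders, Σ|u_i − v_i|^L normalised by the identity-vs-reversal worst case
(L = 1.5 by default), after untangling; and (ii) the tree-vs-tree
cophenetic correlation coefficient, the Pearson correlation of the two
cophenetic distance vectors (the classical tree-vs-data CPCC is a
separate function).  Untangling alternates exact one-sided optimal
ordering — a dynamic program over subtree placements — between the two
trees until no improvement; for ≤ 8 leaves the exhaustive optimum over
all 2^(n−1)×2^(n−1) rotation pairs is computed and adopted, so
8-haplotype comparisons are exact.  The search is deterministic.

## Synthetic cohorts

The generator emulates the study conditions the analyses assume: 63
strains over haplotypes A–H (as even as 63 allows), 21 markers in 4
distinct patterns, two arms (Ctrl / Iso) with 2 animals per strain per
arm, sex alternating within strain, 3 experimenters and 5 library plates
assigned round-robin, 11 traits (7 "static" organ/histology-like, 4
"dynamic" echo-like), and 12,439 nuclear genes with a MitoCarta flag on
a ~9% subset.  Animals per strain per arm is not a literature value; 2
is a free parameter.

Two pattern geometries are available.  `balanced` (default): orthogonal
4/4 Walsh bipartitions of the founders, so the distinct patterns behave
like independent tests — the right regime for threshold calibration
(with 4 patterns the 5% FWER threshold approaches the Šidák value
1 − 0.95^(1/4) ≈ 0.0127).  `nested`: laminar splits ({E–H}, {C,D},
{G,H}, {B}, …) with marker counts decreasing with split depth, mimicking
phylogenetically related founder mt-genomes; this is the geometry in
which trait/sequence tree comparison is meaningful, because orthogonal
patterns make founders near-equidistant and hierarchically degenerate.

Traits are sums of a trait mean, an arm offset, a sex coefficient,
experimenter effects, a strain random effect shared across arms
(SD 0.5), planted marker effects applied through the strain's haplotype
allele and restricted to one arm, and animal noise (SD 1.0, so planted
betas are in noise-SD units).  Counts are negative binomial (dispersion
0.1) around log-normal gene baselines (median ≈ 100 counts) with
log2-scale plate (SD 0.2), sex (SD 0.1), strain (SD 0.15) and planted
arm-specific eQTL effects; planted-eQTL genes have their baseline floored
at 50 counts so a planted effect concerns a gene that survives the depth
filter.  Founder sequences share one random background with marker
alleles at marker positions plus 25 private mutations per founder at
disjoint sites, making pairwise Hamming distances equal the marker
mismatch count plus a constant — sequence trees therefore reproduce the
marker-pattern geometry exactly.  All randomness flows from one seed
through named child streams; a fixed seed reproduces a dataset
bit-identically.

What the generator does *not* emulate: nuclear recombination and the
breeding funnel, heteroplasmy, realistic trait correlation structure
across echo parameters, sequencing depth variation, and count
overdispersion heterogeneity.  Passing tests therefore demonstrate the
statistical machinery under the assumed model, not robustness to the
full messiness of real cohorts.

## Validation experiments

`mitocross.experiments` packages the studies the test-suite and
`scripts/acceptance.py` run; the problem sizes were chosen to keep the
full battery within minutes on one core:

- OLS engine vs an independent normal-equations solve (100 instances).
- FWER calibration on 500 null traits (n_perm = 2,000, FWER 5%), plus
  single-pattern and four-pattern thresholds at n_perm = 10,000 against
  the nominal and Šidák references.
- 1.5-SD planted trait effect and 1.5 log2-unit planted eQTL: detection
  rate over 200 replicates at FWER 5% (arm-specific), mean beta error,
  and the null-gene hit fraction (gene panel of 150 for the eQTL study).
- Dendrogram arm contrast: 200 replicates of a nested-pattern cohort with
  nine 2.5-SD Iso-only dynamic-trait effects spread 4/2/2/1 across the
  four patterns; success requires strictly lower entanglement and higher
  CPCC in the effect arm.
- GSEA: brute-force running-sum agreement, random-set NES centring, and
  top-k set significance.

## Numerical conventions

Two-sided tests throughout; strict inequality at thresholds; p values
clipped into (0, 1]; quantiles are type-7; dosage ties and merge ties
break alphabetically / lexicographically; rank aggregation ties keep the
first contrast; every output table is TSV with a fixed column order and
every run writes a manifest with sha256 hashes of its outputs.
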