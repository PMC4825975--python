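# Methods

This note documents the models, defaults, and numerical choices behind
`oligoheart`, and what the synthetic-data experiments do and do not show.

## Trio inheritance model

A variant call enters the model only if every trio member passes the
filters: panel MAF ≤ `maf_max` (default 0.03; a variant absent from the
panel is treated as rare and retained, since novel alleles cannot be
frequency-filtered), per-member depth ≥ 8, per-member genotype quality
≥ 0.5 on a [0, 1] scale, protein-altering consequence (missense, LoF,
inframe indel), and gene not on the blacklist (mutation-tolerant genes by
RVIS percentile, copy-number-polymorphic genes). All thresholds are
inclusive. A call with a missing genotype in any member is dropped with a
logged reason rather than raising.

Classification is definition-driven: *de novo* requires the proband to
carry an alternate allele with both parents homozygous reference (the
depth filter on parents guards against allele dropout mimicking a de novo
event); *rare homozygous* requires proband hom-alt with each parent
carrying exactly one alternate allele; *compound heterozygous* requires
two heterozygous variants in one gene with opposite, unambiguous parental
origin. Phase is inferred purely by transmission: a variant is maternal
when the mother carries the alternate and the father can have contributed
the reference; a variant both parents carry heterozygously is ambiguous
and never supports a compound-het call. When a gene holds more than one
maternal × paternal combination, one event per pair is emitted but
carrier bookkeeping counts the gene once per individual — case/control
contrasts tally probands, not pairs. Because the variant-counting
convention for pairs is genuinely ambiguous, collation reports both
conventions (each pair member counted, or one per event).

The subnetwork-heat arm applies a stricter MAF cutoff (0.02) than the trio
model (0.03); both are module-level defaults.

QC reports the Ti/Tv ratio over proband SNVs (transitions are
purine↔purine / pyrimidine↔pyrimidine; +inf sentinel with zero
transversions) and the fraction of proband heterozygous genotypes whose
parental origin transmission resolves (NaN with no heterozygotes).

## Coexpression modules

Counts are normalized to log1p counts-per-million; transcripts collapse to
one row per gene by connectivity (sum of absolute correlations with all
rows; ties to the lexicographically smallest transcript id, for
determinism). Module detection uses the unsigned adjacency |cor|^β with
soft power β = 6 — the conventional default for unsigned networks, kept
configurable — topological-overlap dissimilarity, and average-linkage
hierarchical clustering. The tree is cut at a fixed fraction (0.99) of the
tallest merge height with small clusters (< `min_module_size`) pooled as
unassigned; this fixed-height cut is a deterministic, testable stand-in
for the full dynamic-tree-cut heuristic and is sufficient for
planted-block recovery. The module eigengene is the first right singular
vector of the row-standardized module matrix, sign-fixed against the
module mean profile. Because unsigned modules legitimately contain
anticorrelated members, the sign is not informative for tissue
assignment, so a module's tissue is the one with the largest |Pearson
correlation| between eigengene and tissue indicator; signed correlations
are reported alongside. Gene-list augmentation from a second expression
matrix is a generic top-k-by-mean-expression union.

## Heat-diffusion subnetworks

The diffusion operator is F = β (I − (1−β) W)⁻¹ with W the
column-normalized adjacency, computed per connected component; every
column of F sums to 1, so total exchanged heat equals total input heat.
The restart probability β defaults to 0.4 (the usual choice for insulated
diffusion on interactomes; not dictated by any quantity we reproduce).
Exchanged heat E = F·diag(h); directed edges with E above δ are kept and
strongly connected components of size ≥ 2 reported. Pruning is monotone in
δ. Heat is the count of distinct probands with a filtered event per gene
plus a configurable increment per CNV-hit gene — proband counts are robust
to per-individual variant multiplicity. Genes absent from the network are
dropped with a logged count; singleton components cannot form subnetworks.

The null model permutes the network by degree-preserving double edge
swaps (10× the edge count by default); empirical significance per size
class is the fraction of permutations reaching the observed count,
floored at 1/n_perm and capped at 1 (with 100 permutations: [0.01, 1]).
δ candidates are selected per target size as the median over permutations
of the smallest threshold at which the permuted network yields no
subnetwork larger than the target, binary-searched over the sorted edge
weights.

## Burden testing

The score statistic is Q = (y − ŷ₀)ᵀ G W² Gᵀ (y − ŷ₀) with variant
weights the Beta(1, 25) density of the MAF (w = 25(1−p)²⁴ ≈ 25 for
singletons, ≈ 12 at p = 0.03). The null model is an OLS regression of the
phenotype on an intercept plus the top genotype principal components
(default 4) — the linear-kernel variant of the test; a logistic null is
available but small-sample binary-trait corrections are out of scope. MAFs
for weighting come from the reference panel when present, otherwise from
the cohort-observed frequency. Under the null Q follows Σ λ_j χ²₁ with λ
the eigenvalues of σ̂² · W Gᵀ P G W (P the covariate projection);
eigenvalues below 1e-10 of the largest are truncated. The p-value uses
Liu-Tang-Zhang moment matching, switching to Imhof characteristic-function
inversion when one eigenvalue dominates the spectrum (skewness near the
single-χ² bound), where moment matching is least reliable; the Imhof
integral is computed on an eigenvalue-rescaled, panelled finite interval
chosen so the integrand envelope is below 1e-13. With a single variant the
test reduces exactly to the 1-df score test. Measured at n = 633 with 20
variants, the null rejection rate at α = 0.05 is 0.048 (6000 replicates).

Multiple testing is controlled per analysis family with Bonferroni
(α/m; 0.05/86 ≈ 5.81e-04 for the reference subnetwork family). QQ
diagnostics report −log10 observed vs uniform expected quantiles and the
median-based genomic-inflation factor λ_GC; note that at m = 86 this
estimator's null 95% interval is roughly [0.6, 1.6] — wide bands are
expected at small test counts.

## Monte-Carlo gene-set statistics

The observed statistic is the Fisher p for the per-individual carrier
table of the target gene set; replicates redraw same-size gene sets
uniformly from the universe (18,495 protein-coding genes by default) and
the empirical p is (r+1)/(n+1), never zero, minimum exactly 1/(n+1).
"At least as extreme" means replicate p ≤ observed p — chosen as
p-ordering so the direction is scale-invariant. This conservative tie
rule makes the p-value super-uniform when the discrete statistic has
ties; an exact randomized tie-break (lexicographic rank with a uniform
jitter, the standard device for discrete test statistics) is available
via `tie_break="randomized"` and is the variant whose null distribution
is exactly uniform on the grid — the uniformity checks in the test suite
use it, while the conservative rule remains the reporting default.
Two-tailed Fisher uses the probability-ordering convention; one-tailed
(enrichment in cases) is the default for directional claims.

## CNV consensus

Coordinates are half-open 0-based internally (BED), 1-based inclusive in
reports. Calls cluster by single linkage on reciprocal overlap ≥ 0.5
(configurable; 0 means any overlap — both conventions offered because the
agreement criterion in consensus calling is not standardized) within
individual and copy state; a cluster is kept when supported by ≥ 2
distinct callers and its merged span (outer bounds, conservative for
locus-overlap annotation) strictly exceeds 100 kb. Inheritance: a child
call is inherited from a parent with a same-state overlapping call,
de novo when both parents were assayed and carry none, unknown otherwise.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 59 + 59 trios at ~20k coding
sites, 100 + 533 singletons, a 22-tissue expression atlas with 3 libraries
per tissue, and a preferential-attachment interactome (node→name mapping
shuffled so gene names carry no degree information). Panel MAFs follow a
rare-skewed scaled Beta(0.2, 5); founders are Hardy-Weinberg and children
Mendelian. Substitutions are transition-biased at 3.10/4.10 so the
expected Ti/Tv matches the 3.10 of a well-behaved exome call set. Depth is
Poisson(44) (the cohort-scale coverage), quality Uniform with a
configurable passing fraction (0.9 by default). Planted-event rates
default to the observed disease-signal density (~0.3 events per affected
proband, i.e. ~18 events across 59 probands). Planted events are
family-private (absent from all other trios, panel MAF redrawn below
0.01) and forced to pass the depth/quality filters — the truth table
describes detectable signal by construction — and at most one event is
planted per (trio, gene) so compound-het pairs never cross. Planted
module genes receive baselines at or above the atlas mean, as the
well-expressed canonical developmental genes they emulate.

The `noiseless()` preset additionally makes background sites
non-protein-altering, so the consequence filter removes every
non-planted call: in that regime, chance in-trans pairs and chance rare
homozygotes cannot occur and exact recovery (sensitivity 1, FDR 0) is a
meaningful contract. Under the realistic defaults, chance qualifying
events are genuine biology and recovery metrics would not (and should
not) be exact.

Deliberately not modeled: linkage disequilibrium, chemistry-specific
error models, sex-chromosome inheritance, population admixture, SAGE tag
mapping, and genuine annotation (consequence classes are generated
directly, replacing an annotation tool while preserving the filter
surface; the quality score stands in for a proprietary classifier output
and is emulated as a uniform [0, 1] scalar, not a calibrated
probability). Passing tests therefore demonstrate the correctness of the
statistical machinery and bookkeeping on data satisfying the stated
generative assumptions, not robustness to artifacts of real exome data.

## Problem sizes in tests and the acceptance script

Planted-trio recovery runs at the full study scale (59 + 59 trios, 20k
sites). Burden calibration uses 2000 null replicates in the acceptance
script and 4000 in the test suite (n = 633, 20 variants); power uses 100
replicates of the planted two-gene set at effect 8 (a strong enrichment,
case carrier frequencies ~8× controls among rare variants). Subnetwork
recovery uses a 500-node network with 100 permutations; coexpression uses
1500 genes × 66 libraries; exact-test enumeration is exhaustive for table
totals ≤ 25 and randomized up to 60; Monte-Carlo uniformity uses 500
seeds × 199 permutations.
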