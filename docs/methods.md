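# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical edge-case conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Phenotypic heterosis

Mid-parent heterosis MPH% = 100·(F1 − MP)/MP with MP = (P1+P2)/2;
high-parent heterosis HPH% = 100·(F1 − BP)/BP with BP = max(P1, P2).
"High parent" means the parent with the larger trait mean regardless of
agronomic desirability — this is what produces negative HPH entries when
the hybrid falls below the better parent. Both statistics are invariant
to rescaling all three means by a common positive factor.

Significance: the mid-parent sample is built from per-replicate parental
pairs (P1ᵢ+P2ᵢ)/2 (requiring equal parental replicate counts) and compared
to the F1 replicates with a two-sided Welch t-test; HPH compares F1 to the
better parent's replicates. Stars follow ** p < 0.01, * p < 0.05. Welch
was chosen because replicate variances of field traits are rarely equal;
with ≤ 3 replicates the test is conservative, which is the right failure
mode for trait tables. Degenerate identical samples return p = 1.

The packaged trait-table fixture carries two rows whose printed percentage
cannot be reproduced from the printed genotype means (recomputation gives
3.05 vs printed 2.81, and 0.95 vs printed 0.1); they are flagged in a
`note` column and excluded from reference comparisons rather than patched.

## Expression, normalization, and differential calling

FPKM(g,s) = counts(g,s)·10⁹/(total(s)·length(g)) with per-sample column
sums as the mapped-library total, since alignment-level totals are not
available at the count-matrix boundary. The identity
Σ_g FPKM·length/10⁹·total = total holds algebraically and is verified to
float tolerance in the tests.

Differential tests run on log2(FPKM + c), pseudocount c = 1 FPKM, which
bounds log-ratios at zero expression. The default statistic is a pooled
two-sample t with empirical-Bayes variance moderation: per-gene variances
s²_g (df d) are modeled as draws from a scaled-F prior; the prior df d₀
and scale s₀² are estimated by the method of moments on log s² (trigamma
inversion via Newton), and the posterior variance
(d₀s₀² + d s²_g)/(d₀ + d) enters the t-statistic with d + d₀ degrees of
freedom. Rationale: with 3 biological replicates a per-gene Welch t has
~4 df and cannot reach the stringent FDR ≤ 0.005 threshold even for
4-fold changes; pooling variance information across genes is the standard
small-n remedy and keeps the test deterministic. A plain Welch option
remains behind the same interface (`method="welch"`). Genes with zero
counts throughout both groups are reported p = 1, log2 ratio 0.

DEG thresholds are inclusive: |log2 ratio| ≥ 1 and BH-FDR ≤ 0.005
(both configurable; a looser p < 0.05 screen can be expressed through the
same options). BH adjustment is delegated to statsmodels; an independent
step-up implementation serves as the test oracle.

## Mode-of-inheritance decomposition

Model y = u + GA + GD + SR + e per gene on log2(FPKM+1). With genotype
means the estimators are [a] = (m₁ − m₂)/2, [d] = m_F − (m₁+m₂)/2, and
u is reported as the mid-parent mean. The replicate-block effect SR is
estimable only when replicates pair across genotypes; with unpaired
replicates it is dropped and the residual df adjusts accordingly (SR
cancels from both contrasts either way). Standard errors come from the
pooled residual variance: se([a]) = σ√(1/n₁+1/n₂)/2,
se([d]) = σ√(1/n_F + 1/(4n₁) + 1/(4n₂)).

Potency ratio Hp = [d]/[a]; conventions for degenerate estimates:
[a] = 0 with [d] ≠ 0 → signed infinity → over-dominance; both zero → 0 →
additive. Class intervals (half-open on both sides, so ±boundary points
classify asymmetrically, e.g. +0.2 additive but −0.2 partial dominance):
additive (−0.2, 0.2], partial (−0.8, −0.2] ∪ (0.2, 0.8], dominance
(−1.2, −0.8] ∪ (0.8, 1.2], over-dominance (−∞, −1.2] ∪ (1.2, ∞). The
partition covers the extended real line exactly; sign symmetry of the
classification holds everywhere except at the boundary points themselves.

`effects_table` accepts the linear FPKM matrix and applies two
pre-processing steps worth stating:

* **Column calibration (default on).** FPKM is a within-sample relative
  measure; when one genotype's transcriptome shifts in aggregate, every
  gene's cross-genotype contrast inherits a common offset (composition
  bias). Samples are rescaled so their mean log2 expression over the
  everywhere-expressed genes is equal — a geometric-mean size-factor in
  the DESeq spirit. A median-based variant is noisier when effects are
  dense and bimodal (no null-gene backbone), so the mean version is used.
  Calibration happens on the pure log-FPKM scale before the pseudocount,
  because the pseudocount compresses low-expression genes and would leak
  into the offset estimate.
* **Replicate pooling.** When no environment/timepoint restriction is
  given, all conditions' replicates are pooled per genotype. This is the
  right estimator when the additive/dominance architecture is shared
  across conditions (as in the simulator) and simply a larger-n fit
  otherwise; per-condition tables are obtained by passing the
  restriction.

An optional confidence-interval gate marks genes whose 99.8% CI for
[d] − [a] (when [d] > 0) or [d] + [a] (when [d] < 0) excludes zero —
a guard that the dominance deviation is resolvable before interpreting
its ratio. It defaults off because it distorts class proportions (genes
with [d] ≈ [a], i.e. complete dominance, fail it disproportionately).

The class breakdown reports the percentage of genes per mode (summing to
100), optionally grouped, e.g. per environment × timepoint or restricted
to the hybrid-specific SDG_hp set.

## Gene-set logic

SDG = union of up- and down-regulated DEGs of the timepoint contrast
within one genotype and environment (the inputs must be disjoint).
SDG_hp = SDG(F1) \ (SDG(P1) ∪ SDG(P2)): "hybrid-specific" excludes genes
significant in *either* parent — the stricter of the two possible
readings, chosen because a gene also responding in one parent is not a
hybrid-specific response. SSDG_hp intersects the two environments' SDG_hp
sets and is therefore a subset of each. Venn regions are the seven
disjoint membership combinations of three sets and always sum to the
union size.

## Co-expression modules

Gene selection: low-expression genes are removed first (nonzero in ≥ 80%
of samples), then the top 5000 genes by raw median absolute deviation are
kept (ties broken by gene order). Network: unsigned adjacency
a_ij = |cor(xᵢ, xⱼ)|^β with soft power β = 20 — the power is treated as a
fixed study parameter rather than re-derived from scale-free fit, and the
unsigned form is the classical default. Zero-variance genes get
correlation 0 with a warning. Topological overlap:
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(kᵢ, kⱼ) + 1 − a_ij) over u ∉ {i, j},
TOM_ii = 1, clustering input 1 − TOM.

Module detection is average-linkage hierarchical clustering with a
*static* cut, chosen over dynamic tree cutting to keep detection fully
deterministic and specifiable in one number. The default cut is
min(0.99, the 0.995 quantile of merge heights): at β = 20 unrelated genes
sit at TOM dissimilarity ≈ 1, so 0.99 separates any genuinely correlated
block, while the quantile guard keeps the cut inside the dendrogram for
data whose merges all occur lower. Clusters below 30 genes (classical
minimum module size) are pooled into "grey"; labels M1, M2, … order
modules by decreasing size.

The module eigengene is the first principal component across samples of
the gene-standardized module submatrix (via SVD), sign-oriented to
correlate positively with the module's mean standardized profile; a
single-gene module returns that gene's z-score. Eigengene–trait
association is Pearson correlation with two-sided p; constant traits are
reported r = 0, p = 1 with a warning rather than NaN.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for overlap k between an n-gene
query and a K-gene term in an N-gene universe; the universe defaults to
all annotated genes and can be overridden (e.g. intersected with measured
genes). Terms with K < 5 are excluded before testing, BH runs across the
tested terms, and FDR ≤ 0.05 (inclusive) defines significance. Only
over-representation is tested; annotations are treated as flat sets with
no ontology-graph propagation.

## Synthetic-data generator

The generator emulates a replicated two-parent/one-hybrid field
experiment: 3 genotypes × 2 environments × 2 timepoints × 3 replicates =
36 libraries by default, ~20M expected reads each, NB counts with
variance μ + φμ² (φ = 0.1 default; φ = 0 is the Poisson limit). Neither
the dispersion nor the depth of the motivating study is published, so
both are configurable defaults at typical bulk-RNA-seq values.

Per gene, a baseline log2 level is drawn uniformly on [3, 10]; genotype
means follow P1 = m + a, P2 = m − a, F1 = m + d on the log2 scale
(effects multiplicative on counts, matching fold-change-based calling).
Sign convention: a > 0 means the first-listed parent is higher. The
magnitude |a| equals `effect_scale` (default 1, i.e. 4-fold parental
difference); d = Hp·a with |Hp| drawn from a *continuous piecewise-linear
density* over the class intervals (knots at 0, 0.2, 0.8, 1.2, 3) whose
per-interval areas equal the configured class proportions exactly
(largest-remainder allocation of gene counts). The continuous density
was chosen over per-class uniform blocks because real potency ratios are
not piecewise-uniform with jumps at classification thresholds, and a
density jump at a class boundary makes any finite-noise estimate of the
class *proportions* biased by construction (net probability flux across
the boundary) — an artifact of the benchmark, not of the estimator.
Degenerate mixes that admit no nonnegative continuous density (e.g. a
single class) fall back to per-class uniform draws.

Planted structure on top of the trio architecture:

* **Temporal responders.** Chosen genes get a ±`sdg_shift` (default 2,
  i.e. 4-fold, comfortably above the 2-fold calling threshold) log2 shift
  at the later timepoint, either in all three genotypes
  (`n_sdg_parent_shared`) or in the hybrid only
  (`n_sdg_hybrid_specific`), in a configurable subset of environments;
  the truth table records SDG/SDG_hp/SSDG_hp flags per environment.
* **Co-expression blocks.** Each `module_spec` entry (size, r) adds a
  latent per-sample N(0,1) factor with loading 0.5·√(r/(1−r)), calibrated
  against the ~0.5 log2-units of NB count noise so the realized
  within-block correlation approximates r. Module genes are drawn
  disjoint from SDG genes.
* **Annotations.** `generate_annotation` builds a GMT-style term map over
  the simulated universe with one term constructed to overlap a target
  set at a configured rate.

Expected per-sample totals are scaled to the library size exactly;
because FPKM is invariant to per-column scale, planted log2 effects
survive normalization (up to the composition offsets discussed above,
which the calibration removes). Everything is driven by one
`numpy.random.default_rng(seed)`, so identical configs give bit-identical
outputs.

What the simulator does **not** emulate — and hence what passing recovery
tests do not establish about real data: read-level artifacts (no FASTQ,
alignment or positional bias), gene-length/GC coupling to expression,
batch or lane effects beyond an optional replicate block, unbalanced or
missing replicates, isoform mixtures, and effect sizes correlated with
expression level. Recovery rates measured here are upper bounds for
field data.

## Problem sizes in the shipped checks

The test suite and acceptance checks run, by design, at desk scale:
5,000 genes × 36 libraries for inheritance-mode recovery, 2,000 genes for
DEG/SDG recovery, 600 genes with three 60-gene blocks for module
recovery, 200 annotation draws for the enrichment benchmark, and the
16-row packaged trait table for heterosis. These sizes were chosen so
each statistical claim is measured with comfortable Monte-Carlo margin
while the whole suite completes in well under a minute of compute; the
pipeline itself is vectorized and handles transcriptome-scale matrices
(the only quadratic-memory stage is the gene × gene TOM, which at the
conventional 5,000-gene selection occupies ~200 MB).

## Known limitations

* The moderated t assumes a common variance prior across genes; strong
  mean–variance trends (as in very low-count data) are not modeled — a
  count-model alternative (exact NB) could sit behind the same interface.
* The potency-ratio classifier is a point-estimate rule; near class
  boundaries, replicate noise flips assignments, and per-gene class
  labels should be read with the reported standard errors in mind even
  when aggregate proportions are accurate.
* Static tree cutting will split very close module pairs or merge
  modules bridged by intermediate genes where the dynamic hybrid cut
  might not; the cut height is exposed for that reason.
* The Venn/set layer treats gene identity as exact strings; no cross-
  annotation identifier mapping is attempted.
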