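# Methods

This note records the statistical models implemented in `methsub`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would need
to know.

## Preprocessing

Each probe's beta values (strictly in (0,1)) are residualized by ordinary
least squares on an intercept plus covariates; categorical covariates are
dummy-coded and rank deficiency is reported with the names of the collinear
columns. Residualization operates on betas by default; an M-value (logit)
option exists but is off, since the clustering consumes beta-scale
residuals. The non-variant-probe filter uses, per probe, the 90th
percentile of absolute deviations from the probe median (linear
interpolation between order statistics); probes whose statistic exceeds a
configurable quantile cutoff of that statistic's distribution (default
0.5) are retained. The original retained fraction is not derivable from a
published threshold, so the quantile is an explicit parameter. At cutoff
quantile 0, the threshold is taken as exactly zero so that every probe
with positive spread survives; this keeps filtering monotone in the cutoff.

## Cluster discovery

Ward-D2 clustering is scipy's `ward` linkage on raw Euclidean distances
(the ward.D2 convention — distances are not pre-squared by the caller);
k-means uses 25 seeded restarts. Two k-selection rules are provided:

* `elbow_select` — k maximizing the second forward difference of the WCSS
  curve; a knee below 0.3 times the curve's total drop flags a
  low-confidence (structureless) selection. This is one of several knee
  heuristics; the maximal-second-difference form is used because it is
  parameter-free.
* `select_k_by_nmi` — k maximizing hierarchical-vs-k-means NMI. Exact NMI
  ties are generic on well-separated data (consistently merging or
  splitting clusters keeps agreement at 1), so ties are broken by WCSS
  curvature among the tied k, not by "smallest k", which systematically
  under-segments.

The pipeline's `choose_k` composes the two the way the discovery procedure
is described: the WCSS elbow proposes the cluster number — specifically the
largest k whose relative curvature (second difference over total sum of
squares) exceeds 1% — and the NMI at that k validates method agreement
(flagged below 0.3). Pure max-NMI selection is biased toward merging: on
data with a genuine small third cluster, collapsing it into a neighbor
raises the agreement of the two methods while destroying the structure of
interest, which is why curvature drives the choice and NMI audits it.

NMI normalization defaults to "max" ("sqrt"/"mean"/"min" configurable);
the normalization used by the original analysis tooling is not documented.
Consensus labels use optimal (Hungarian) one-to-one matching of the
contingency table, making consensus deterministic; letters A, B, C… follow
hierarchical-cluster order.

## Sparse PLS-DA

Labels are dummy-coded, features centered and scaled by training
statistics. Per component the dominant direction of X'Y Y'X is found by
power iteration (deterministic init from the largest-norm column of X'Y;
orientation fixed by making the largest-magnitude weight positive),
soft-thresholded at the (keep+1)-th largest absolute weight so exactly
`keep_per_component` features stay nonzero, and renormalized; X and Y are
deflated by regression on the component scores, which makes scores exactly
orthogonal. Projection uses the regression-form rotation R = W(PᵀW)⁻¹ so
self-projection reproduces training scores to machine precision. Model
defaults are 6 components × 2,000 features (the documented total of 12,000
split evenly — the natural reading of the tool interface that reports only
the total); the replication pipeline uses 2 components × 200 features
because hulls live on components 1–2 and the synthetic studies carry a few
thousand probes rather than hundreds of thousands.

Features absent from a projection target (e.g. an older array platform)
are dropped from the rotation and each component rescaled by the inverse
retained squared-weight mass; projection refuses to run when under half of
the selected features are available. Replication data are centered/scaled
with *discovery* statistics — self-consistent with the rotation, at the
cost of sensitivity to cohort-level mean shifts.

The randomization-robustness procedure permutes the labels of a fraction p
of samples (grid 1.00, 0.75, 0.50, 0.25, 0.10, 0.05, 0.01 — only the
endpoints of the original grid are documented), refits, and reports the
fraction of the reference selection recovered; draws producing a class
with fewer than two samples are redrawn.

## Cross-cohort replication

Median profiles are computed per consensus cluster on covariate-residualized
values (not raw betas): residualization removes the per-cohort probe
baseline, so cross-cohort profile correlations reflect the cluster-specific
deviations rather than the shared baseline, which would otherwise push all
correlations toward 1 and blunt the matching. A block requires mutual best
correlation in **every** cohort pair; weaker chain schemes were rejected
for determinism. Hull membership uses the qhull facet inequalities with a
1e-9 tolerance, so boundary points count as inside; collinear clusters
fall back to a zero-width segment. The hypergeometric test is the
one-sided upper tail P(X ≥ observed) with N = all replication samples,
K = samples inside the hull, n = replication-cluster size; BH correction is
applied within each discovery→replication rotation (the original analysis
states no multiplicity rule; 0.05 after BH is the declared default). A
point inside two overlapping hulls counts for both. Confirmation demands
every ordered cohort pair within a block, under both clustering methods;
confirmed blocks are named LOAD-S1, LOAD-S2, … in block order.

## Co-methylation modules

The full weighted-network pipeline (topological overlap, dynamic hybrid
tree cut, block-wise processing) is deliberately replaced by a simplified
detector: signed adjacency a = ((1+r)/2)^power (power 6), average-linkage
clustering of 1−a, cut at height 0.8, minimum module size 10. The cut
height is calibrated to the adjacency scale: with power 6, dissimilarity
0.8 corresponds to within-module correlations around 0.5, a realistic
co-methylation strength, while uncorrelated probes sit near 0.97.
Eigenprobes are the first right singular vector of the per-probe
standardized module matrix, sign-oriented to correlate positively with the
module mean profile. Cross-platform preservation recomputes eigenprobes on
the probe subset; a module is preserved iff the cluster-label ANOVA stays
significant on both versions (p < 0.05) and a per-cluster paired t-test
between versions is non-significant everywhere (the same samples underlie
both eigenprobes, hence paired). With many samples the paired test is
sensitive to very small systematic differences, so "not preserved" is a
strict verdict; this is inherent to the declared test.

## EWAS and meta-analysis

Per-CpG OLS returns the outcome coefficient, its standard error, the Wald
statistic and a two-sided p on the residual-df t reference. Surrogate
variables come from permutation parallel analysis of the residual matrix:
row-permuted data are re-residualized on the design (the null must live in
the same subspace) and variance-matched to the observed residuals; because
within-row permutation samples without replacement, its nulls are slightly
deflated, and a component must exceed the null 95th percentile by a factor
1.05 to count (calibrated so pure noise yields zero surrogates in ≥ 90% of
runs while a planted batch is always found).

The bias/inflation correction fits a three-component normal mixture to the
z-scores by EM rather than a Gibbs sampler — the contract is parameter
recovery, not sampler equivalence. The central component is the one with
the largest weight; after each M-step the side components' means are pushed
to at least 2 central-sd away from the central mean, which prevents the
sides from eating the central tails (without the constraint the inflation
estimate biases low by a few percent). bias = central mean, inflation =
central sd; corrected quantities are estimate_c = estimate − bias·se and
se_c = se·inflation, so z_c = (z − bias)/inflation exactly (the original
tool's back-transformation is not documented; this one is self-consistent).
On 50,000 draws from N(0.15, 1.25) the EM recovers bias within ±0.03 and
inflation within ±0.05.

Meta-analysis defaults to fixed-effect inverse variance; DerSimonian–Laird
random effects (tau² from Q) is available, avoiding a REML optimizer
dependency. The Bonferroni denominator is the number of CpGs entering the
meta-analysis (CpGs observed in a single cohort are reported unpooled and
excluded from the family).

## Enrichment

Overlap odds ratios are the conditional maximum-likelihood estimates of the
noncentral hypergeometric odds ratio (scipy's `odds_ratio`,
kind="conditional") — the value classical Fisher-test reporting prints,
slightly below the sample odds ratio; an independent grid-search likelihood
oracle in the tests confirms agreement within 0.5%. Enrichment p-values
are one-sided upper-tail hypergeometric; two-sided Fisher is available.
Regulatory intervals follow the 0-based half-open BED convention (position
100 is inside [100, 200); 200 is not); malformed intervals are rejected at
parse. BH families are per subtype set (regulatory features) and per panel
family (cell types × specificity levels).

## Colocalization

Per-SNP log approximate Bayes factors follow the Wakefield form
labf = ½·log(se²/(se²+W²)) + ½·z²·W²/(se²+W²) with prior effect sd
W = 0.15 and priors p1 = p2 = 1e-4, p12 = 1e-5 — the conventional
quantitative-trait defaults, since none are documented for this analysis.
Hypothesis sums use log-sum-exp; H3's double sum is the product of the
marginal sums minus the diagonal, in log space. The decision rule is
PP(H3)+PP(H4) > 0.90 as stated, even though H4-only is the common
convention; an `h4_only` flag exists. Standard errors may be reconstructed
from p, allele frequency and sample size. Note the posteriors are *not*
invariant to rescaling beta and se alone — the shrinkage ratio depends on
se/W — but are exactly invariant when W is rescaled with them.

## Expression

TMM uses a 30% log-ratio trim, 5% absolute-expression trim,
precision-weighted (delta-method) mean of M values, reference = library
whose upper quartile is closest to the mean, and factors normalized to
geometric mean 1. logCPM adds a prior count of 0.5 *scaled by effective
library size*, so a pure depth change leaves logCPM exactly invariant.
The moderated t shrinks per-gene residual variances toward a prior
estimated by method of moments on log variances (trigamma inversion by
Newton); when the observed log-variance spread is no larger than its
sampling noise the prior df is infinite and the common variance is the
geometric mean, making equal-variance data an exact fixed point. The
consensus DEG rule is: consistent log2FC sign in all three cohorts, linear
|FC| > 1.5 in at least one (the log/linear scale being undocumented,
linear is the declared reading), p < 0.05 in all, FDR < 0.05 in at least
one. CpG–gene candidate pairs lie within TSS ± 10 kb inclusive; Spearman
correlations are computed per (cohort, subtype) stratum with BH within the
stratum, and a pair replicates when FDR < 0.1 in at least two cohorts.

## Microglia and morphology

Pseudobulk is the gene-wise sum over a state's cells per sample. States
with fewer than 100 cells in any group are excluded before proportion
testing (ANOVA + Tukey HSD). The control-anchored PCA normalizes with a
control-referenced TMM (reference sample chosen among controls, factors
left unnormalized) so that nothing about the disease samples can alter the
controls' normalized values — the projection contract is that only
control-derived statistics define the space. Outlier screening measures
distance from the median control score vector over the components
explaining ≥ 80% of control variance, removing controls beyond
median + 3.5×MAD (MAD with the 1.4826 consistency constant); the PCA is
refit on the cleaned controls and all samples are projected with the
control rotation. The separation statistic is the median over all
cross-group sample pairs in PC1–PC2 (a centroid-distance option exists;
the original statistic is not defined precisely). Permutations preserve
group sizes; p = (1 + #{null ≥ obs})/(1 + n_perm), never zero; the
2.5/97.5 null percentiles are reported as the band; BH across group pairs.
Activation scores are the marker-gene logCPM PC1 oriented to correlate
positively with mean marker expression, standardized against controls.
The pseudobulk DEA rule flags a gene iff p < 0.05 in the subtype-vs-subtype
contrast and p < 0.05 in at least one subtype-vs-control contrast (the
stated lenient threshold). Morphology uses Welch t with Satterthwaite df,
Cohen's d with pooled sd, and one BH family per measure across all regions
and group pairs.

## Synthetic data

The generator reproduces the statistical structure each stage assumes, per
cohort on the logit scale: per-CpG baseline N(0, 1.2); covariate terms
with per-probe coefficients (age, sex, neuronal proportion, batch);
planted disjoint CpG signatures (S1 200, S2 200, shared-LOAD 100,
cohort-specific 150, tangle-associated 150 CpGs by default) with fixed
per-CpG effect signs shared across cohorts; Gaussian noise (sd 0.5, with
40% of background probes near-constant at sd 0.05 to exercise the variance
filter); and an inverse-logit map, so betas stay strictly in (0,1) without
clipping. Three forms of within-cluster heterogeneity make the clusters
realistic rather than point masses: a per-sample severity factor
N(1, 0.2) scaling the carried effect, a subclinical gradient N(0, 0.25)
along *every* signature axis in *every* sample (this is what makes
disease-axis CpGs variable enough to pass spread filters in all cohorts,
and what gives discovery-cluster hulls realistic width), and three dense
latent factors (loading sd 0.1) shared across cohorts. Effect sizes
default to 1.5 logits for the subtype signatures and 1.0 for the
cohort-specific cluster. The last cohort exposes a uniform random 60%
probe subset (each signature guaranteed ≥ 50% retained); the
cohort-specific cluster lives in cohort 1 only, on CpGs disjoint from the
subtype signatures, so the Unassigned path is exercised deterministically.

Expression is negative-binomial (dispersion 0.1) with log-normal library
factors, 100 planted DEGs per subtype at fold change 2 with random
directions, and 50 CpG-linked genes whose log-mean tracks the sample's
beta at a planted S2 CpG (slope 6 per beta unit) in LOAD-S2 samples, TSS
placed within 10 kb of the CpG. Microglia: multinomial state cell counts
(totals 500–3,000 per sample), one state made rare (< 100 cells) in one
group, log-normal pseudobulk with +2 log2 marker elevation per state and a
+1 log2 marker shift for state MG2 in LOAD-S1. Morphology draws PAM from
moment-matched Beta distributions per group (LOAD-S1 configured with 4×
the LOAD-S2 variance). One root seed streams named per-component
sub-seeds, so any fixed configuration is byte-identical across runs.

What the generator does **not** emulate: probe-probe correlation beyond
the planted axes (no CpG-island block structure), array measurement error
models (no detection-p or bead-count artifacts), realistic minor-allele or
cell-composition confounding beyond linear covariates, read-level counts,
or LD between SNPs in the colocalization inputs. Passing tests therefore
demonstrate the statistical machinery under the planted-model assumptions,
not performance on raw array data.

## Problem sizes

The standard synthetic study uses 5,000 CpGs and ~150 LOAD samples plus 50
controls per cohort across three cohorts — large enough for every stage to
behave asymptotically while the full discovery→replication pipeline runs
in about a second. Calibration suites use 1,200-CpG studies (50 null
replicates), 50,000 z-scores for the mixture correction, and 1,000
replicates × 500 permutations for the separation-test type-I rate.

## Known limitations

* The hull-based sample-level replication is sensitive to cohort-level
  mean shifts along directions the discovery model selects; with discovery
  scaling (the documented choice) a cohort lacking a discovery-specific
  cluster projects off that cluster's hull center. Realistic within-cluster
  spread absorbs this; data with stronger batch structure would need
  cross-cohort harmonization upstream.
* The simplified module detector is not WGCNA: no topological overlap, no
  dynamic tree cut; module boundaries on weakly correlated data will
  differ from the full pipeline.
* The EM mixture correction assumes a dominant null component; in data
  where true signals outnumber nulls the central-component identification
  fails by design.
* Random-effects meta-analysis uses DerSimonian–Laird, not REML.
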