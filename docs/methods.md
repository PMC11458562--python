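# Methods

This note documents the statistical models implemented in `neuroscca`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Sparse canonical correlation analysis

The core solver maximizes `uᵀXᵀYv` subject to `‖u‖₂ = ‖v‖₂ = 1`,
`‖u‖₁ ≤ τ₁`, `‖v‖₁ ≤ τ₂` by alternating maximization in the
penalized-matrix-decomposition style: each half-step computes the
cross-product direction (`XᵀYv` or `YᵀXu`), soft-thresholds it, and rescales
to the unit sphere. The threshold δ is found by bisection so the L1 budget
binds exactly when active (`l1_constrain`); when the unit-L2 direction
already satisfies the budget, δ = 0. Because each half-step solves its
subproblem exactly, the objective is non-decreasing across iterations —
asserted on every fixture in the test suite.

Choices worth knowing about:

* **Equality L2 constraint.** The weight vectors are renormalized to
  `‖·‖₂ = 1` exactly (rather than `≤ 1`); for nonzero cross-products the
  maximizer lies on the sphere anyway, and equality makes
  ρ = corr(Xu, Yv) well defined.
* **Initialization** is the leading singular pair of `XᵀY` (deterministic);
  `init="random"` with a seed exists for robustness checks. The sign
  convention (largest-|u| entry positive) makes fits bitwise reproducible.
* **Raw cross-product.** `XᵀY` is used unscaled; dividing by (n−1) rescales
  the objective without moving the optimum.
* **Scaling.** Genotype columns are mean-imputed and z-scored before the
  fit, so the L1 budget treats SNPs comparably across allele frequencies.
  Only the imaging side is covariate-adjusted by default (OLS residuals
  against an intercept plus age, sex, education and ICV, then z-scored);
  `adjust_x=True` residualizes the genotype side as well.
* **Degenerate ties.** If the largest |entries| of the cross-product tie
  exactly, the soft-threshold family cannot bind the L1 budget (its L1/L2
  ratio is piecewise constant); the projection falls back to spreading
  weight equally over the ⌊τ²⌋ largest entries, the feasible limit of the
  family. Ties are measure-zero for real data; the branch exists so the
  solver is total.
* **Single component.** Only the rank-1 pair is computed; deflation for
  further components is out of scope.
* τ defaults to the inactive bound √dim; `tune_tau` selects (τ₁, τ₂) from a
  grid by k-fold out-of-fold projection correlation, breaking ties toward
  the sparser pair.

With inactive budgets and column-orthonormal data (Sxx = Syy = I) the
solution coincides with classical CCA's first canonical pair; the test
suite verifies agreement to 1e-4 against an independent eigendecomposition
oracle. On general data the diagonal-covariance approximation intrinsic to
this family means ρ is a penalized, not classical, canonical correlation.

## Genotype QC

Filters run in a fixed order, each on the survivors of the previous stage —
samples: call rate ≥ 0.95, heterozygosity within ±5 SD of the sample mean
(two-sided by default; an excess-only flag exists because "excess
heterozygosity" could be read one-sided), relatedness; markers: call rate
≥ 0.98, MAF ≥ 0.01, HWE exact p ≥ 1e-6, imputation quality r² > 0.8 when
recorded. Every removal is logged with stage, entity, value and threshold.

* **HWE exact test**: the conditional test that sums, over heterozygote
  counts compatible with the observed allele counts, the probabilities not
  exceeding the observed configuration's. Computed in log-space (gammaln)
  so it is exact at any sample size; no mid-p correction. Verified
  exhaustively against direct factorial enumeration for all tables with
  total ≤ 50.
* **Relatedness**: method-of-moments PI_HAT = P(IBD=2) + ½P(IBD=1) from
  pairwise IBS counts, with the expected IBS-given-IBD terms evaluated at
  sample allele frequencies over the jointly observed markers. Only the
  final PI_HAT is clipped to [0, 1]: clipping the per-state probabilities
  first inflates unrelated pairs (verified by simulation). The estimator's
  noise floor scales like 1/√(markers), so the conventional 0.125 cutoff
  presumes genome-wide data; on a few-hundred-SNP panel only near-duplicate
  detection is powered, and the demo pipeline accordingly screens at 0.45.
  For each flagged pair the member with the lower call rate is dropped
  (tie → lexicographically smaller ID), deterministically.
* **Missing genotypes** downstream of QC are mean-imputed per SNP; the
  matrix factorizations require complete data and missingness after QC is
  ≤ 2% by construction.
* Sex-mismatch checking is out of scope (no sex-chromosome data in the
  panel); a precomputed exclusion list can be applied upstream.

## Candidate selection

SNPs with summary-statistic p < 1e-4 (strict) are clumped greedily in
PLINK's style: ascending p, each unassigned SNP becomes an index and
absorbs unassigned SNPs within 250 kb with dosage r² ≥ 0.1. The r²/window
defaults are configurable; they were chosen to make the panel
"uncorrelated" in the conventional sense. Ties in p break by (chrom, pos,
id) so results are order-invariant. Summary statistics join the panel by
rsID only; allele harmonization is out of scope.

## Predictive validation

`fit_elastic_net_cv` runs repeated k-fold cross-validation (default 5 folds
× 10 repeats): per repeat, out-of-fold predictions are pooled and
correlated with the observed outcome; the reported r is the mean over
repeats, with a Fisher-z CI at the sample count. Hyperparameters (mixing
∈ {0.1, …, 1.0}, 50 path alphas) are tuned by a nested 5-fold grid inside
each training fold via `ElasticNetCV`.

The cross-group designs train in one amyloid group with its top-10 SNPs and
test on the other group. These models carry the **SNPs alone** by default:
age and ICV predict thickness in every group, so including them masks
exactly the group-specificity the comparison is designed to expose (with
covariates included, train and test r are both ≈0.8 on the synthetic
cohort and indistinguishable). The within-group model comparison uses three
specifications — covariates only; covariates + top-10 SNPs; covariates +
10 random panel SNPs drawn excluding the top-10 — with ICV as the
anatomical covariate for the thickness outcome and education for MMSE and
CDR-SB, following standard norms for these measures.

Model pairs are compared with the Hittner–May–Silver z for two dependent
overlapping correlations: Fisher-z transform r12 and r13, evaluate the
Dunn–Clark covariance at the backtransformed mean correlation,
z = (z12 − z13)·√((n−3)/(2−2c̄)). The c̄ approximation degenerates as the
correlations approach 1 (c̄ ≥ 1 raises an explicit error rather than
returning NaN). Type-I error is verified at 0.05 ± 0.015 over 2000 null
replicates, with uniform null p-values (KS).

## Mediation

The estimator is the simulation-based ("quasi-Bayesian") two-model
procedure: a logistic mediator model M ~ SNP + covariates and a linear
outcome model Y ~ SNP + M + covariates are fit by maximum likelihood; 1000
parameter vectors are drawn from each model's asymptotic sampling
distribution; per draw, ACME = β_M · (E[M(treat)] − E[M(control)]) averaged
over the observed covariates, ADE = β_T · (treat − control), total = sum.
Point estimates are draw means, CIs are 2.5/97.5 percentiles, and the
two-sided p is twice the smaller tail fraction (capped at 1). The treatment
contrast is one alternate allele (0 → 1), configurable. With the linear,
no-interaction outcome model, ACME + ADE = total holds exactly per draw.
A `mediator_model="linear"` mode exists as a degenerate check: there ACME
reduces to the product of coefficients a·b, verified against that closed
form. Covariates are age, sex, education and ICV; the CU/AD logistic
association uses age, sex and education (no ICV) and excludes aMCI.
Null coverage of the 95% ACME interval is verified to lie in [92%, 98%]
over 200 replicates at n = 2000.

The mediation screen runs every (SNP, ROI) pair with a per-pair seed
derived from the pair's identity (CRC of "snp|roi" mixed with the global
seed), so results are deterministic and invariant to the order in which
pairs are listed. Significance marks use unadjusted p < 0.05 for display
parity with per-pair screening conventions; BH-adjusted q columns are
always emitted alongside. Complete separation in the logistic association
falls back to a ridge-penalized fit and flags the result instead of
failing.

## Enrichment

One-sided (over-representation) Fisher exact test per gene set on the 2×2
table (query∩set, query∖set, set∖query, remainder), with the universe
defaulting to the union of all genes in the GMT — an Enrichr-like choice,
configurable to an annotation-derived background. Odds ratios use the
Haldane–Anscombe 0.5 correction when any cell is zero. q-values are
Benjamini–Hochberg (statsmodels). SNP→gene mapping joins a user-supplied
mapped/nearest-gene table, deduplicating while preserving first-seen order.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is exercised under.

* **Genotypes.** Two independent latent standard-normal haplotype vectors
  per sample, block-diagonal AR(1) across SNPs (block size 8); an allele is
  present when the latent value falls below Φ⁻¹(MAF), MAF ~ U(0.05, 0.5).
  Hardy–Weinberg proportions therefore hold exactly per SNP while
  within-block r² is tuned by `ld_rho`. The default `ld_rho = 0.3` gives
  neighbour r² ≈ 0.05 — the residual correlation of a panel that has
  already been clumped at r² < 0.1, which is what the 344-SNP default panel
  represents; clumping and relatedness tests construct high-LD panels
  explicitly. Blocks are laid out 1 kb apart with 10 Mb gaps, cycling over
  the 22 autosomes.
* **Cohort.** n = 1125 by default with age ~ N(70.2, 8.5²), 58.5% female,
  APOE ε4 counts ~ (0.564, 0.344, 0.092). Education ~ N(11.8, 4.6²) years
  and ICV ~ N(1450, 130²) cm³ are plausible placeholders (no source values
  exist for them) and are configurable. Amyloid positivity follows a
  logistic model with per-causal-allele log-odds `path_a = 0.15` (OR ≈
  1.16, GWAS-scale), a strong APOE ε4 term (log-OR 1.3) and a small age
  term; the intercept is calibrated by bisection so the positive fraction
  hits 57.5%.
* **Thickness.** Twelve ROI columns (five lobes + global mean, both
  hemispheres) with anatomically plausible baselines, covariate slopes
  (age −0.010 mm/yr, small sex/ICV terms), the planted canonical signal,
  an amyloid term `path_b = −0.05` mm, an optional direct SNP term, and
  i.i.d. N(0, 0.1²) mm noise. The planted signal rescales the latent score
  X_std·u_true to unit sample variance before multiplying by
  `canonical_strength`, so the planted correlation has the closed form
  s/√(s² + σ²) regardless of LD — verified against simulation. The default
  s = 0.0735 puts the planted correlation at 0.5 net of the amyloid-path
  variance along v_true. u_true has one causal SNP per LD block with
  magnitudes U(0.75, 1.25) (comparable contributions) and random signs;
  v_true weights the hemispheric global means most heavily, then frontal
  and parietal cortex — the atrophy-loading pattern this kind of analysis
  recovers.
* **Group-specific mode.** `group_signal="disjoint"` plants two disjoint
  causal sets whose signals are active only within the respective amyloid
  group. Cross-group experiments use `canonical_strength = 0.12`, which
  puts the within-group planted correlation near 0.73 — the regime in which
  a within-group train r around 0.75 collapses out of group, the signature
  the validation design exists to detect.
* **Cognition and diagnosis.** MMSE and CDR-SB are noisy linear functions
  of global thickness (clipped to their scales); diagnosis labels (CU /
  aMCI / DAT) cut a latent severity score at the marginal proportions
  310 : 368 : 447 per 1125.
* **Companions.** Summary statistics give causal SNPs log-uniform p below
  1e-4, a configurable fraction (default 0.9) of non-causal SNPs likewise
  (decoys), the rest U(1e-4, 1). The annotation maps each LD block to one
  synthetic gene symbol; the GMT contains one set collecting the causal
  genes plus random sets.

What the generator does **not** emulate: realistic demography or coalescent
LD decay, haplotype phase, sex chromosomes, genotyping batch effects,
site/scanner effects in thickness, longitudinal structure, or
non-Gaussian measurement error. Tests passing on this cohort show the
pipeline's statistical machinery is correct and calibrated under its
assumed model; they are not evidence about effect sizes in real cohorts.

## Problem sizes and determinism

Test and demo problem sizes (n = 260–600, p = 64–172 for pipeline runs;
n = 500–2000 for calibration simulations; 50 seeds for recovery sweeps)
were chosen so the full suite and the acceptance script each complete in a
few minutes on one core while keeping Monte-Carlo error well inside the
asserted tolerances. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the pipeline writes a manifest of parameter
and content hashes, skips stages whose inputs are unchanged, and keeps
wall-clock timings in the log file only, so identical seeds reproduce every
table byte for byte.

## Known limitations

* Support recovery at panel scale is noise-limited: with 10 causal SNPs at
  a planted canonical correlation of 0.5 and n = 500, the per-SNP signal
  (ρ/√10 ≈ 0.16) sits close to the extreme order statistics of ~330 null
  correlations (SE ≈ 0.045), so the top-10 list typically recovers 7–8 of
  10 planted SNPs and recovery of ≥ 8 in ≥ 90% of seeds is not attainable
  in this regime — a larger cohort or stronger signal is required.
* The Hittner c̄ approximation is unreliable when the two compared
  correlations differ wildly or approach 1; the implementation raises
  rather than extrapolating.
* Mediation assumes sequential ignorability; no sensitivity analysis,
  multiple mediators, or treatment–mediator interaction is provided.
* Exact replication of hosted-service enrichment results is impossible
  without their library versions; the local Fisher test is exact for the
  supplied GMT and universe.
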