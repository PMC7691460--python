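# Methods

## Scope and data model

`sprucegs` analyzes multi-site full-sib progeny trials: a pedigree (parents
with unknown ancestry, progeny from controlled crosses), biallelic SNP
genotypes coded as minor-allele counts 0/1/2 with missing values, and a
phenotype table with tree, site, test nested in site, age, and trait columns.
Right-skewed metabolite traits are square-root transformed before modelling
and all downstream quantities (heritabilities, correlations, gains) are
reported on that analysis scale; a back-transform is deliberately not applied
to gains because the percentage-of-mean scale is not invariant under it.

## Relationship matrices

- **A** (pedigree): tabular method in topological order;
  `A_ii = 1 + 0.5 A(sire,dam)`, unknown parents contribute zero. Entries are
  exact rational numbers for textbook pedigrees and are tested as such.
- **G** (genomic, VanRaden): columns centred by twice the observed allele
  frequency, scaled by `2 Σ p(1-p)`. Frequencies come from all genotyped
  trees (progeny plus genotyped-only candidates), matching
  realized-relationship practice. Monomorphic markers are excluded from
  numerator and denominator.
- **G_Dom** (genomic dominance): per-marker covariates
  `{-2p², 2pq, -2q²}` for genotypes `{0,1,2}`, scaled by `Σ (2pq)²`. Which
  homozygote receives `-2p²` is a marker-orientation convention; G_Dom is
  invariant to it.
- `condition_psd` adds a small ridge (default 1e-6, plus the eigenvalue
  deficit) only when the minimum eigenvalue is non-positive, and records that
  it did.

## SNP quality control

Per-SNP statistics: call rate; MAF on non-missing calls; fixation index
`Fe = 1 - Hobs/Hexp` with `Hexp = 2pq` (undefined for monomorphic markers,
which the MAF filter removes anyway); replicate discordance when replicate
pairs exist; Mendelian checks as (a) the fraction of genotyped trios with an
impossible child genotype and (b) a chi-square test of full-sib segregation
ratios per informative family (≥5 informative offspring), Bonferroni-adjusted
across families. Default thresholds: missingness <15%, MAF ≥0.01, |Fe| <0.5,
error rate <2%, Mendel alpha 0.001 with a hard fail at ≥1% impossible trios.
A SNP is retained iff it passes every filter; attrition is attributed to
filters in application order, but the retained set itself is order-invariant
(tested).

## LD-kNN imputation

For each missing call (tree i, SNP s): take the `l` SNPs with highest r² to s
(r² from complete pairs only, to avoid imputation circularity); the distance
from i to any tree observed at s is the mean absolute genotype difference
over those SNPs (pairs observed on both sides), offset by +1 so a perfect
match keeps a finite, maximal weight; the `k` nearest trees vote for a
genotype in {0,1,2} with weights 1/d². Defaults `l=30, k=5`. SNPs with fewer
than `k` observed calls, or cells with no finite-distance neighbour, fall
back to the modal genotype (logged). Observed calls are never altered and
the transform is idempotent on complete matrices.

## REML engine

A dense average-information (AI) REML with:

- one variance per random term (additive; optional dominance) plus one
  residual variance per site;
- AI updates with step-halving; components pushed negative are pinned to the
  floor and the AI system re-solved in the remaining subspace; any step that
  would decrease the restricted likelihood falls back to an EM update, which
  is monotone;
- negative variances projected to a floor of 1e-8 (the trait is standardized
  internally, so the floor is scale-free; results are returned on the
  original scale);
- convergence when |Δloglik| < 1e-6 and the relative change of all interior
  parameters (those not at the floor) < 1e-8; a diagnostic error carrying the
  iteration trace is raised if the likelihood is still moving at the
  iteration cap.

BLUPs for *all* individuals in the relationship matrix (phenotyped or not)
come from `θ K[:, obs] P y`, which is how unphenotyped candidates and
held-out cross-validation trees are predicted: they enter only through their
relationship rows. Standard errors of heritabilities use the delta method
with the inverse-AI covariance of the variance components; whether the
reference software used this or a bootstrap is not documented, and the AI
covariance is the standard choice.

Dense linear algebra is a deliberate choice: trials of a few thousand trees
fit easily, and exact trace terms keep AI/EM updates simple and robust.

## Bivariate models

Additive (and additive-dominance) bivariate fits use the CORGH
parameterization: per-trait variances plus one correlation for each of the
additive, dominance and residual structures. Per the reference model
specification, the bivariate residual is homogeneous across sites (2×2
structure), unlike the univariate fits. The additive-only model is fitted in
an eigenbasis of the kinship submatrix, where the likelihood factorizes into
n 2×2 blocks (O(n) per evaluation); the AD model maximizes the dense stacked
likelihood. Correlations are optimized on the atanh scale, variances on the
log scale, started from univariate fits with correlations at 0. Derived
quantities:

```
rg = (ra·σa1·σa2 + rd·σd1·σd2) / sqrt((σa1²+σd1²)(σa2²+σd2²))
rp = (ra·σa1·σa2 + rd·σd1·σd2 + re·σe1·σe2) / sqrt(Πt (σat²+σdt²+σet²))
```

with the family-variance parameterization contributing `4σ_f²` to the
genetic denominator. Significance uses likelihood-ratio tests against
reduced fits with the relevant correlations fixed at zero (χ² with df =
number of fixed correlations); the SE of ra is delta-method from a
finite-difference Hessian.

## Hypothesis tests and model comparison

Variance-component LRTs use the boundary mixture 0.5·χ²₀ + 0.5·χ²₁; the
reported p-value is `0.5·P(χ²₁ > t)`, so a statistic of exactly zero reports
p = 0.5. Type-I error of this test is verified by simulation (1,000 null
replicates; rate ≤ 7% at α = 0.05). AIC = −2ℓ + 2k and
BIC = −2ℓ + k·ln(n − rank X) count only the k variance parameters, with
residual degrees of freedom in BIC (a documented choice; the reference
analysis does not state its convention).

## BayesCπ

Gibbs sampler with joint (indicator, effect) updates from the marginalized
likelihood ratio — single-site indicator updates mix poorly, the joint
update does not. Per iteration: fixed effects (flat prior, coordinate-wise),
each marker's indicator+effect, slab variances (scaled-inv-χ², df 5), π per
term (Beta conjugate, prior mean 0.5, weight 10), per-site residual
variances (scaled-inv-χ², df 5). Slab scales follow the common R² heuristic:
the prior marker variance explains R² = 0.5 of the phenotypic variance,
split equally across the additive and dominance terms. The production
schedule is 50,000 iterations, 15,000 burn-in, thinning 20, two chains with
derived seeds; a reduced schedule (5,000/1,500/5) is used in tests and the
acceptance script. Convergence is the two-chain Gelman–Rubin PSRF (floored
at 1.0; values < 1 are sampling noise) with the usual <1.1 rule. The sampler
kernel is numba-compiled and bit-reproducible given the seed and schedule.
Two limits are verified: with π forced to 1 and the slab fixed, posterior
means match ridge-regression BLUP; a single planted QTL attains the top
inclusion probability among null markers.

## Cross-validation

Folds are stratified within full-sib family (members shuffled, dealt
round-robin with a running offset so small families also spread), k = 10
folds × 10 repeats in the production design. Adjusted phenotypes y* are the
residuals of the fixed-effects-only least-squares fit, computed once on the
full data (refitting per training fold changes PA by less than its Monte
Carlo error on simulated data and the single-fit definition matches the
reference procedure). PA is the Pearson correlation of held-out predictions
with y*. PACC variant 1 divides PA by √h² (additive models) or √H² (AD
models), always taken from the full-data *genomic* fit so model classes are
compared on the same scale; the full-data h² is used rather than per-fold
refits (the reading adopted for an ambiguous procedure description).
Variants 2 and 3 correlate fold predictions with full-data ABLUP and GBLUP
values as pseudo-truths; they are known to run optimistic and are reported,
not headlined. Failed fold fits are recorded and excluded from means.

## Selection

Selected-set size is round-half-up of intensity × candidate count (5% of
1,516 → 76). Ranking ties break by stable id order, so every strategy is
deterministic. Gains are `100 · mean(predicted value of selected) /
phenotypic mean` on the analysis scale. Independent culling discards
candidates below secondary-trait thresholds before ranking on the primary
trait; the index standardizes each trait's predictions to z-scores over the
candidate set before weighting (the candidate-set SD is the only scale the
data offer); correlation breakers keep the sign constraint on the secondary
trait and fill the full target size from qualifying candidates, flagging a
shortfall instead of failing.

## Synthetic trial generator

The generator emulates the reference trial design: 120 dams × 118 sires
crossed into 136 distinct full-sib families, 10 phenotyped progeny per
family (~1,360 trees) plus 206 genotyped-only progeny; 5 sites, 4 tests per
site, one test per family per site, ~80% of families on two sites; test ages
uniform in 16–28 years; 4,148 SNPs by default, founder MAF uniform in
(0.05, 0.5), LD from an AR(1) Gaussian copula within 20-SNP blocks,
transmission of whole parental blocks per gamete (no within-block
recombination — a modelling shortcut, not a recombination map); missingness
0.4% and genotyping errors 0.02% as in the reference assay.

Breeding values are sums of random marker effects on the gene-dropped
genotypes, drawn with a 7-trait correlation structure (growth traits
positively correlated; piceol–pungenol +0.60; pungenol–picein −0.65; weak
negative growth–aglycone correlations), so their covariance matches
`σa²·ra ⊗ A` in expectation while staying coherent with the markers that
GBLUP and BayesCπ see. A Cholesky-of-A route is available when genotypes are
not wanted. Dominance defaults to a full-sib family effect (variance σd²/4)
plus an individual deviation (3σd²/4) — full sibs share a quarter of the
dominance variance, and the family-effect ABLUP parameterization recovers
σ_f² ≈ σd²/4; a marker-coded dominance mode exists for genomic-dominance
studies. Per-trait targets (means, dispersions, h², d²) follow the published
trait summaries; per-site residual variances are not published, so defaults
scale a base residual SD by factors 0.8–1.25 across sites, chosen once to
give coefficients of variation in the published range. Metabolite traits are
emitted as squared latent values (their latent means sit 2σ above zero, so
the sign fold is negligible), which reproduces the right skew and makes the
square-root transform the correct preprocessing.

What the generator does **not** emulate: genotype-by-environment
interaction (not estimable in the reference design and excluded here),
trait-specific phenotyping subsets, multi-generation breeding, spatial
within-test correlation, and selection history in the parents. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to those real-data features.

## Problem sizes used in tests and the acceptance script

Unit tests run on trials of ~600 phenotyped trees and 200–600 SNPs.
Parameter-recovery checks use ~2,000 phenotyped trees (20 replicates for the
h² = 0.5 target; one bivariate fit for ra = 0.6); LRT calibration uses 1,000
null replicates of a 150-tree, 30-family trial. The acceptance script runs
the study-like configuration with 1,500 SNPs, 5-fold × 2-repeat
cross-validation and the reduced BayesCπ schedule; these sizes are the
package's default demonstration scale and all reported quantities are
recomputed at run time.

## Known limitations

- Dense O(n³) REML; practical to ~5,000 trees, not for national evaluations.
- The bivariate AD optimizer is derivative-free on 9 parameters and is the
  slowest fit in the package; use the additive bivariate model unless
  dominance correlations are specifically needed.
- PACC variants based on pseudo-true values inherit the optimism of that
  definition; compare models on PA/√h².
- Fe-based filtering assumes the sample approximates Hardy-Weinberg
  proportions; in strongly structured panels |Fe| flags structure, not
  genotyping error.
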