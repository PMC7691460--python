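# sprucegs

Genomic selection for conifer breeding trials: relationship matrices,
REML/BLUP mixed models, BayesCπ marker models, cross-validated prediction
accuracy, and multi-trait selection scenarios — with a synthetic
breeding-trial generator for end-to-end validation.

## The problem

Breeding white spruce for resistance to the spruce budworm hinges on two
needle metabolites, the acetophenone aglycones **piceol** and **pungenol**,
which are heritable but expensive to phenotype (LC-MS on needle extracts).
Genomic selection sidesteps the phenotyping bottleneck: train a prediction
model on a subset of trees that are both genotyped and phenotyped, then rank
every genotyped candidate — including trees never measured — on its predicted
breeding value. `sprucegs` implements the full analysis such a program needs,
for multi-site full-sib progeny trials of the type run by tree improvement
cooperatives: hundreds of parents, full-sib families planted across several
sites with tests nested in site, tree age as a covariate, and a few thousand
array SNPs.

## The models

Phenotypes follow the individual-tree mixed model

```
y = Xβ + Z₁a + (Z₂d) + e,   a ~ N(0, σ²ₐ K),   e ~ N(0, R)
```

where β holds the mean, site, test-within-site and age effects; K is the
pedigree relationship matrix **A** (ABLUP) or the VanRaden genomic matrix
**G** (GBLUP); the optional dominance term uses a full-sib family effect
σ²_f·I (ABLUP) or the genomic dominance matrix **G_Dom** (GBLUP); and R is
block-diagonal with one residual variance per site. Estimation is
average-information REML with EM fallback. Individual-scale heritabilities
are h² = σ²ₐ/(σ²ₐ + σ²_d + σ̄²ₑ), d² = σ²_d/(…) (or 4σ²_f/(σ²ₐ+σ²_f+σ̄²ₑ) under
the family parameterization), with delta-method standard errors. Bivariate
fits estimate additive/dominance/residual correlations (CORGH: a correlation
plus per-trait variances) and derive total genetic and phenotypic
correlations.

The BayesCπ sampler puts a spike-and-slab prior on marker effects (additive:
minor-allele counts; dominance: heterozygosity indicator) with the inclusion
proportion π given a Beta prior and estimated; GEBVs are sums of
posterior-mean marker effects, so unphenotyped candidates are scored
directly. Convergence is monitored with the Gelman–Rubin shrink factor over
multiple chains.

Model quality is assessed by family-stratified 10×10-fold cross-validation:
predictive ability PA = cor(predicted values, fixed-effect-adjusted
phenotypes y*) and prediction accuracy PACC = PA/√h² (plus two
pseudo-true-value variants). Selection scenarios (truncation, independent
culling, equal-weight index, correlation breakers) report expected per-trait
gains as a percentage of the phenotypic mean and the number of full-sib
families represented.

## Worked example

```python
from sprucegs.simdata import default_config, simulate_trial
from sprucegs.genoqc import compute_snp_stats, filter_snps, impute_ldknni
from sprucegs.kinship import vanraden_G
from sprucegs.mixedmodel import fit_univariate, heritability

cfg = default_config(seed=1, n_snps=1500)     # study-like trial
ped, geno, pheno, truth = simulate_trial(cfg)

stats = compute_snp_stats(geno, pedigree=ped)
retained, attrition = filter_snps(stats)       # missingness, MAF, |Fe|, Mendel
geno = impute_ldknni(geno.subset(snps=sorted(retained)))

G = vanraden_G(geno)
fit = fit_univariate(pheno, G, trait="PICEOL", transform="sqrt")
h = heritability(fit)
print(f"GBLUP h2 = {h.h2:.3f} ± {h.se_h2:.3f}")
```

prints (seed 1):

```
GBLUP h2 = 0.391 ± 0.031
```

i.e. the genomic model recovers a narrow-sense heritability near the 0.43
simulated for the piceol-like trait, with its delta-method standard error.
The same objects feed cross-validation (`sprucegs.crossval.run_cv`), marker
models (`sprucegs.bayescpi.BayesCPi`) and selection
(`sprucegs.selection.select_top`, `expected_gains`, …). A `sprucegs` CLI
wraps the common steps (`simulate`, `qc`, `impute`, `kinship`, `fit`, `run`).

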