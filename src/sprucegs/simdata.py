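"""Synthetic breeding-trial generator.

Emulates a multi-site full-sib progeny trial of the kind used in conifer
breeding programs: ~212 elite parents crossed into 136 full-sib families,
~1,300 phenotyped progeny plus a set of genotyped-only trees, five sites
with tests nested in site, tree age as a covariate, a few thousand SNPs in
LD blocks with low missingness, site-heterogeneous residual variances,
right-skewed metabolite traits (emitted on the squared scale so the
analysis-side square-root transform applies), and a 7-trait genetic
correlation structure.

The generator returns the true parameters and values (breeding values,
dominance deviations, realized heritabilities and genetic correlations)
needed for parameter-recovery tests.

Randomness: every public operation derives an independent child stream from
``config.seed`` so outputs are bit-identical across runs with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TraitSpec",
    "TruthSet",
    "default_config",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_trial",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class TraitSpec:
    """Target parameters for one simulated trait, on the analysis scale.

    ``h2_target`` and ``d2_target`` are the narrow-sense and dominance
    fractions of the model-scale phenotypic variance
    (sigma_a^2 + sigma_d^2 + mean sigma_e^2); site/test/age effects sit on
    top of that variance, as they are absorbed by fixed effects in the
    analysis. ``skew_transform='square'`` emits the squared latent value so
    the analysis applies a square-root transform to recover it.
    """

    name: str
    mean: float
    h2_target: float
    d2_target: float = 0.0
    site_effect_sd: float = 1.0
    test_effect_sd: float = 0.5
    residual_sd_by_site: tuple = (1.0,)
    age_slope: float = 0.0
    skew_transform: str = "none"  # none | square
    genetic_corr: tuple = (1.0,)  # this trait's row of the correlation matrix

    def variance_components(self) -> tuple[float, float, float]:
        """(sigma_a^2, sigma_d^2, mean sigma_e^2) implied by the targets."""
        sig_e2 = float(np.mean(np.square(self.residual_sd_by_site)))
        resid_frac = 1.0 - self.h2_target - self.d2_target
        if resid_frac <= 0:
            raise ConfigError(f"{self.name}: h2_target + d2_target must be < 1")
        sig_p2 = sig_e2 / resid_frac
        return self.h2_target * sig_p2, self.d2_target * sig_p2, sig_e2


@dataclass
class SimConfig:
    n_females: int = 120
    n_males: int = 118
    n_families: int = 136
    progeny_per_family: int = 10
    n_unphenotyped: int = 206
    n_sites: int = 5
    tests_per_site: int = 4
    age_range: tuple = (16, 28)
    n_snps: int = 4148
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 20
    missing_rate: float = 0.004
    genotyping_error_rate: float = 0.0002
    single_site_family_fraction: float = 0.2
    dominance_mode: str = "family"  # family | marker
    trait_specs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        counts = dict(
            n_females=self.n_females,
            n_males=self.n_males,
            n_families=self.n_families,
            progeny_per_family=self.progeny_per_family,
            n_sites=self.n_sites,
            tests_per_site=self.tests_per_site,
            n_snps=self.n_snps,
            ld_block_size=self.ld_block_size,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be > 0 (got {v})")
        if self.n_unphenotyped < 0:
            raise ConfigError("n_unphenotyped must be >= 0")
        for name in ("missing_rate", "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1] (got {v})")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must be within (0, 0.5] (got {self.maf_range})")
        if self.n_families > self.n_females * self.n_males:
            raise ConfigError(
                f"{self.n_families} families infeasible with "
                f"{self.n_females} x {self.n_males} parents"
            )
        for spec in self.trait_specs:
            if not 0.0 <= spec.h2_target <= 1.0 or not 0.0 <= spec.d2_target <= 1.0:
                raise ConfigError(f"{spec.name}: h2/d2 targets must be in [0, 1]")
            if spec.h2_target + spec.d2_target > 1.0:
                raise ConfigError(f"{spec.name}: h2_target + d2_target > 1")
            if len(spec.residual_sd_by_site) != self.n_sites:
                raise ConfigError(
                    f"{spec.name}: residual_sd_by_site must have length n_sites"
                )
            if spec.skew_transform not in ("none", "square"):
                raise ConfigError(f"{spec.name}: unknown skew_transform")
        if self.trait_specs:
            R = self.genetic_corr_matrix()
            if np.linalg.eigvalsh(R)[0] < -1e-8:
                raise ConfigError("genetic correlation matrix is not PSD")

    def genetic_corr_matrix(self) -> np.ndarray:
        T = len(self.trait_specs)
        R = np.array([list(s.genetic_corr) for s in self.trait_specs], dtype=float)
        if R.shape != (T, T) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ConfigError("trait genetic_corr rows must form a correlation matrix")
        return R

    def trait_names(self) -> list[str]:
        return [s.name for s in self.trait_specs]


@dataclass
class TruthSet:
    """Simulation truth retained for parameter-recovery oracles."""

    true_breeding_values: pd.DataFrame  # all individuals x traits (analysis scale)
    true_dominance_deviations: pd.DataFrame
    realized_h2: pd.Series
    realized_ra: pd.DataFrame

    def __post_init__(self):
        for df in (self.true_breeding_values, self.true_dominance_deviations):
            if not np.isfinite(df.to_numpy()).all():
                raise ValueError("truth values must be finite")


# ---------------------------------------------------------------------------
# default study-like configuration


_TABLE_LIKE = [
    # name, mean(analysis scale), sd(analysis scale), h2, d2, age_slope, transform
    ("HT", 1119.0, 203.0, 0.25, 0.14, 25.0, "none"),
    ("DBH", 155.0, 33.0, 0.13, 0.10, 4.0, "none"),
    ("VOL", 10.5, 5.3, 0.13, 0.12, 0.4, "none"),
    ("VELO", 3.53, 0.39, 0.41, 0.25, 0.01, "none"),
    ("PICEOL", 2.46, 1.0, 0.43, 0.05, 0.0, "square"),
    ("PUNGENOL", 1.90, 1.1, 0.57, 0.08, 0.0, "square"),
    ("PICEIN", 12.1, 9.6, 0.64, 0.0, 0.0, "none"),
]

# additive genetic correlations among the seven traits (lower triangle),
# order HT, DBH, VOL, VELO, PICEOL, PUNGENOL, PICEIN
_RA_LOWER = [
    [1.0],
    [0.44, 1.0],
    [0.66, 0.83, 1.0],
    [0.06, 0.03, -0.04, 1.0],
    [-0.38, -0.25, -0.24, -0.20, 1.0],
    [-0.14, 0.07, 0.06, -0.04, 0.60, 1.0],
    [-0.11, -0.21, -0.23, -0.20, -0.03, -0.65, 1.0],
]

#: per-site residual scale factors (heterogeneous residual variances)
_SITE_FACTORS = np.array([0.80, 0.90, 1.00, 1.10, 1.25])


def _nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w[0] >= floor:
        return R
    Rn = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(Rn))
    return Rn / np.outer(d, d)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Configuration mirroring the reference breeding-trial design."""
    T = len(_TABLE_LIKE)
    R = np.eye(T)
    for i in range(T):
        for j in range(i + 1):
            R[i, j] = R[j, i] = _RA_LOWER[i][j]
    R = _nearest_correlation(R)
    specs = []
    for t, (name, mean, sd, h2, d2, slope, transform) in enumerate(_TABLE_LIKE):
        sig_p = 0.9 * sd  # model-scale share of the observed spread
        resid_sd = sig_p * np.sqrt(max(1.0 - h2 - d2, 0.05))
        specs.append(
            TraitSpec(
                name=name,
                mean=mean,
                h2_target=h2,
                d2_target=d2,
                site_effect_sd=0.3 * sig_p,
                test_effect_sd=0.15 * sig_p,
                residual_sd_by_site=tuple(np.round(resid_sd * _SITE_FACTORS, 6)),
                age_slope=slope,
                skew_transform=transform,
                genetic_corr=tuple(np.round(R[t], 6)),
            )
        )
    return SimConfig(trait_specs=specs, seed=seed, **overrides)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Mate founders into distinct full-sib families and drop progeny.

    Founders (dams ``F###``, sires ``M###``) have unknown parents. Each
    family is a unique (dam, sire) pair with ``progeny_per_family``
    phenotyped progeny; ``n_unphenotyped`` additional genotyped-only progeny
    are spread over randomly chosen families.
    """
    rng = _rng(config, 1)
    dams = [f"F{i + 1:03d}" for i in range(config.n_females)]
    sires = [f"M{i + 1:03d}" for i in range(config.n_males)]
    pair_idx = rng.choice(
        config.n_females * config.n_males, size=config.n_families, replace=False
    )
    pairs = [(dams[k // config.n_males], sires[k % config.n_males]) for k in pair_idx]

    rows = [
        {"id": d, "sire": None, "dam": None, "sex": "F", "cohort": 0,
         "family": None, "phenotyped": False}
        for d in dams
    ] + [
        {"id": s, "sire": None, "dam": None, "sex": "M", "cohort": 0,
         "family": None, "phenotyped": False}
        for s in sires
    ]

    fam_of_extra = rng.integers(0, config.n_families, size=config.n_unphenotyped)
    counter = 0
    for f, (dam, sire) in enumerate(pairs):
        fam = f"fam{f + 1:03d}"
        n_extra = int(np.sum(fam_of_extra == f))
        for k in range(config.progeny_per_family + n_extra):
            counter += 1
            rows.append(
                {
                    "id": f"P{counter:05d}",
                    "sire": sire,
                    "dam": dam,
                    "sex": None,
                    "cohort": 1,
                    "family": fam,
                    "phenotyped": k < config.progeny_per_family,
                }
            )
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genotypes


def _founder_haplotypes(rng, n_hap: int, p: np.ndarray, block: int) -> np.ndarray:
    """Gaussian-copula haplotypes: SNPs within a block share an AR(1) latent."""
    from scipy.stats import norm

    m = len(p)
    H = np.empty((n_hap, m), dtype=np.int8)
    thresh = norm.ppf(p)
    rho = 0.9
    for start in range(0, m, block):
        L = min(block, m - start)
        C = rho ** np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        z = rng.standard_normal((n_hap, L)) @ np.linalg.cholesky(C).T
        H[:, start : start + L] = (z < thresh[start : start + L]).astype(np.int8)
    return H


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes through the pedigree.

    Founder haplotypes are drawn with allele frequencies uniform in
    ``maf_range`` and within-block LD from a latent AR(1) Gaussian copula.
    Progeny inherit one parental haplotype per LD block and gamete (no
    recombination within a block). Genotyping errors and missingness are
    injected at the configured rates; the pre-masking truth is retained on
    the returned matrix as ``truth_values``.
    """
    rng = _rng(config, 2)
    n, m = pedigree.n, config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    blocks = np.arange(m) // config.ld_block_size
    n_blocks = int(blocks[-1]) + 1
    block_sizes = np.bincount(blocks)

    hap = np.zeros((n, 2, m), dtype=np.int8)
    founder_rows = np.where(pedigree.is_founder)[0]
    H = _founder_haplotypes(rng, 2 * len(founder_rows), p, config.ld_block_size)
    hap[founder_rows, 0] = H[: len(founder_rows)]
    hap[founder_rows, 1] = H[len(founder_rows) :]

    for i in pedigree.topo_order:
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s < 0 and d < 0:
            continue
        for gamete, parent in enumerate((d, s)):
            if parent < 0:  # unknown parent: draw a population haplotype
                hap[i, gamete] = _founder_haplotypes(rng, 1, p, config.ld_block_size)[0]
            else:
                choice = np.repeat(rng.integers(0, 2, size=n_blocks), block_sizes)
                hap[i, gamete] = np.where(choice == 0, hap[parent, 0], hap[parent, 1])

    truth = (hap[:, 0, :] + hap[:, 1, :]).astype(np.float64)

    observed = truth.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random((n, m)) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=int(err.sum()))
        observed[err] = np.mod(observed[err] + shift, 3)
    if config.missing_rate > 0:
        observed[rng.random((n, m)) < config.missing_rate] = np.nan

    gm = GenotypeMatrix(
        ids=pedigree.ids,
        snp_ids=np.asarray([f"snp{j + 1:05d}" for j in range(m)]),
        values=observed,
    )
    gm.truth_values = truth
    return gm


# ---------------------------------------------------------------------------
# traits


def _assign_sites(rng, families: np.ndarray, config: SimConfig):
    """Family-to-site layout: 1-2 sites per family, one test per site.

    Reproduces the confounding of the reference design, where dominance
    (family) effects are partially confounded with test effects because each
    family occupies a single test on any site it appears on.
    """
    fams = pd.unique(families)
    fam_sites: dict = {}
    fam_tests: dict = {}
    for fam in fams:
        if rng.random() < config.single_site_family_fraction or config.n_sites == 1:
            sites = rng.choice(config.n_sites, size=1, replace=False)
        else:
            sites = rng.choice(config.n_sites, size=2, replace=False)
        fam_sites[fam] = sites
        fam_tests[fam] = {s: int(rng.integers(config.tests_per_site)) for s in sites}
    site_of = np.empty(len(families), dtype=np.int64)
    test_of = np.empty(len(families), dtype=np.int64)
    for fam in fams:
        rows = np.where(families == fam)[0]
        picks = fam_sites[fam][rng.integers(0, len(fam_sites[fam]), size=len(rows))]
        site_of[rows] = picks
        test_of[rows] = [fam_tests[fam][s] for s in picks]
    return site_of, test_of


def simulate_traits(
    pedigree: Pedigree, config: SimConfig, genotypes: GenotypeMatrix | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate correlated phenotypes over the pedigree.

    Breeding values are sums of random marker effects on the (true)
    gene-dropped genotypes when ``genotypes`` is given — their covariance
    across individuals then matches ``sigma_a^2 * ra (x) A`` in expectation —
    and a Cholesky-of-A multivariate-normal draw otherwise. Dominance is a
    full-sib family effect (variance ``sigma_d^2 / 4``) plus an individual
    deviation (``3 sigma_d^2 / 4``) by default, or marker-coded
    (heterozygosity covariates) with ``dominance_mode='marker'``.

    Phenotype = mean + site + test(site) + age_slope * (age - midpoint)
    + a + d + site-specific residual; traits with ``skew_transform='square'``
    are emitted squared.
    """
    if not config.trait_specs:
        raise ConfigError("config.trait_specs is empty")
    rng = _rng(config, 3)
    specs = config.trait_specs
    T = len(specs)
    R = config.genetic_corr_matrix()
    w, V = np.linalg.eigh(R)
    R_chol = (V * np.sqrt(np.maximum(w, 0))) @ V.T  # symmetric square root

    sig_a = np.sqrt([s.variance_components()[0] for s in specs])
    sig_d = np.sqrt([s.variance_components()[1] for s in specs])

    n = pedigree.n
    ids = pedigree.ids

    # --- breeding values ---------------------------------------------------
    if genotypes is not None:
        M = getattr(genotypes, "truth_values", None)
        if M is None:
            M = np.nan_to_num(genotypes.values)
        M = M[genotypes.index_of(ids)]
        pfreq = M.mean(axis=0) / 2.0
        poly = (pfreq > 0) & (pfreq < 1)
        W = M[:, poly] - 2.0 * pfreq[poly]
        scale = np.sqrt(2.0 * np.sum(pfreq[poly] * (1 - pfreq[poly])))
        alpha = (rng.standard_normal((W.shape[1], T)) @ R_chol.T) / scale
        bv = W @ alpha * sig_a
    else:
        from .kinship import pedigree_to_A

        A = pedigree_to_A(pedigree).values
        wA, VA = np.linalg.eigh(A)
        L = VA * np.sqrt(np.maximum(wA, 0))
        bv = L @ (rng.standard_normal((n, T)) @ R_chol.T) * sig_a

    # --- dominance deviations ---------------------------------------------
    families = pedigree.family_codes().to_numpy()
    dom = np.zeros((n, T))
    if config.dominance_mode == "marker" and genotypes is not None:
        M = getattr(genotypes, "truth_values", np.nan_to_num(genotypes.values))
        M = M[genotypes.index_of(ids)]
        pfreq = M.mean(axis=0) / 2.0
        poly = (pfreq > 0) & (pfreq < 1)
        pq = pfreq[poly] * (1 - pfreq[poly])
        Mp = M[:, poly]
        H = np.where(
            Mp == 1, 2 * pq, np.where(Mp == 0, -2 * pfreq[poly] ** 2, -2 * (1 - pfreq[poly]) ** 2)
        )
        delta = (rng.standard_normal((H.shape[1], T)) @ R_chol.T) / np.sqrt(
            np.sum((2 * pq) ** 2)
        )
        dom = H @ delta * sig_d
    else:
        fams = pd.unique(pd.Series(families).dropna())
        fam_eff = rng.standard_normal((len(fams), T)) @ R_chol.T * (0.5 * sig_d)
        fam_pos = {f: k for k, f in enumerate(fams)}
        indiv = rng.standard_normal((n, T)) @ R_chol.T * (np.sqrt(0.75) * sig_d)
        for i in range(n):
            if families[i] is not None and not pd.isna(families[i]):
                dom[i] = fam_eff[fam_pos[families[i]]] + indiv[i]

    # --- field layout and phenotypes ---------------------------------------
    pheno_mask = (
        pedigree.table["phenotyped"].to_numpy(dtype=bool)
        if "phenotyped" in pedigree.table.columns
        else ~pedigree.is_founder
    )
    rows = np.where(pheno_mask)[0]
    site_of, test_of = _assign_sites(rng, families[rows], config)
    lo, hi = config.age_range
    age_by_test = {
        (s, t): int(rng.integers(lo, hi + 1))
        for s in range(config.n_sites)
        for t in range(config.tests_per_site)
    }
    ages = np.array([age_by_test[(s, t)] for s, t in zip(site_of, test_of)])
    mid_age = 0.5 * (lo + hi)

    out = pd.DataFrame(
        {
            "tree": ids[rows],
            "family": families[rows],
            "site": [f"S{s + 1}" for s in site_of],
            "test": [f"S{s + 1}T{t + 1}" for s, t in zip(site_of, test_of)],
            "age": ages,
        }
    )
    resid = np.zeros((len(rows), T))
    for t, spec in enumerate(specs):
        site_eff = rng.normal(0.0, spec.site_effect_sd, size=config.n_sites)
        test_eff = rng.normal(
            0.0, spec.test_effect_sd, size=(config.n_sites, config.tests_per_site)
        )
        e = rng.normal(0.0, 1.0, size=len(rows)) * np.asarray(
            spec.residual_sd_by_site
        )[site_of]
        resid[:, t] = e
        latent = (
            spec.mean
            + site_eff[site_of]
            + test_eff[site_of, test_of]
            + spec.age_slope * (ages - mid_age)
            + bv[rows, t]
            + dom[rows, t]
            + e
        )
        out[spec.name] = latent**2 if spec.skew_transform == "square" else latent

    total = bv[rows] + dom[rows] + resid
    realized_h2 = pd.Series(
        np.var(bv[rows], axis=0) / np.var(total, axis=0), index=config.trait_names()
    )
    with np.errstate(invalid="ignore"):
        realized_ra = pd.DataFrame(
            np.corrcoef(bv[rows].T) if T > 1 else np.ones((1, 1)),
            index=config.trait_names(),
            columns=config.trait_names(),
        )
    truth = TruthSet(
        true_breeding_values=pd.DataFrame(bv, index=ids, columns=config.trait_names()),
        true_dominance_deviations=pd.DataFrame(
            dom, index=ids, columns=config.trait_names()
        ),
        realized_h2=realized_h2,
        realized_ra=realized_ra,
    )
    return out, truth


def simulate_trial(config: SimConfig):
    """Convenience wrapper: pedigree, genotypes, phenotypes and truth."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    pheno, truth = simulate_traits(ped, config, genotypes=geno)
    return ped, geno, pheno, truth
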