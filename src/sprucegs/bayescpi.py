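"""BayesC-pi Gibbs sampler for marker-effect genomic selection models.

Marker effects get a spike-and-slab prior: each effect is zero with
probability 1 - pi and Gaussian with a common slab variance otherwise; pi
itself has a Beta prior and is estimated per term. The additive term uses
minor-allele counts (0/1/2), the optional dominance term a heterozygosity
indicator (0/1). Fixed effects (mean, site, test-within-site, age) carry a
flat prior; the residual has one variance per site. Indicators and effects
are updated jointly from the marginalized likelihood ratio, so mixing does
not suffer from the usual single-site sticking.

Hyperpriors follow common whole-genome-regression defaults: slab and
residual variances are scaled-inverse-chi-square with df 5 and scales set
from an R^2 = 0.5 heuristic split equally across terms; pi ~ Beta with
prior mean 0.5 and weight 10. All are configurable.

Predictions are plain sums of posterior-mean marker effects over the
genotype codes, so unphenotyped genotyped candidates are scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeMatrix
from .mixedmodel import _transform_y, build_fixed_design

__all__ = [
    "BayesCpiConfig",
    "MarkerEffects",
    "BayesCPi",
    "fit_bayescpi",
    "gelman_rubin",
    "predict_from_markers",
]


@dataclass
class BayesCpiConfig:
    """Sampler schedule and priors (schedule defaults: long production run)."""

    n_iter: int = 50000
    burn_in: int = 15000
    thin: int = 20
    n_chains: int = 2
    p0: float = 10.0  # Beta prior weight for pi
    pi0: float = 0.5  # Beta prior mean for pi
    df0: float = 5.0  # slab variance prior df
    r2: float = 0.5  # heuristic share of variance assigned to markers
    dfe: float = 5.0  # residual variance prior df
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.p0 <= 0 or not (0 < self.pi0 < 1):
            raise ValueError("pi prior requires p0 > 0 and pi0 in (0, 1)")

    @classmethod
    def reduced(cls, **kw) -> "BayesCpiConfig":
        """Short schedule for tests and quick exploration."""
        kw.setdefault("n_iter", 5000)
        kw.setdefault("burn_in", 1500)
        kw.setdefault("thin", 5)
        return cls(**kw)


@dataclass
class MarkerEffects:
    snp_ids: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray | None
    inclusion_prob_a: np.ndarray
    inclusion_prob_d: np.ndarray | None
    pi_hat_a: float
    pi_hat_d: float | None
    gebv: pd.Series
    gegv: pd.Series | None
    psrf: pd.Series
    traces: list  # per chain: DataFrame of monitored parameters


@njit(cache=True)
def _gibbs(y, X, Z1, Z2, site_idx, n_sites, n_iter, burn_in, thin,
           df0, S0a, S0d, dfe, Se, p0, pi0, seed, use_dom, pi_fixed_a,
           slab_fixed):
    np.random.seed(seed)
    n, p = X.shape
    m = Z1.shape[1]
    beta = np.zeros(p)
    a = np.zeros(m)
    d = np.zeros(m)
    sig_a = S0a
    sig_d = S0d if use_dom else 0.0
    pi_a = pi0 if pi_fixed_a < 0 else min(max(pi_fixed_a, 1e-9), 1.0 - 1e-9)
    pi_d = pi0
    ve = np.full(n_sites, Se)
    e = y.copy()
    n_s = np.zeros(n_sites)
    for i in range(n):
        n_s[site_idx[i]] += 1.0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    n_trace = 4 + n_sites + (2 if use_dom else 0)
    traces = np.zeros((n_keep, n_trace))
    sum_a = np.zeros(m)
    sum_d = np.zeros(m)
    freq_a = np.zeros(m)
    freq_d = np.zeros(m)
    kept = 0

    for it in range(n_iter):
        w = 1.0 / ve[site_idx]
        # fixed effects, flat prior, coordinate-wise
        for j in range(p):
            c = 0.0
            rhs = 0.0
            for i in range(n):
                c += X[i, j] * X[i, j] * w[i]
                rhs += X[i, j] * e[i] * w[i]
            rhs += c * beta[j]
            new = rhs / c + np.random.normal() / np.sqrt(c)
            diff = beta[j] - new
            for i in range(n):
                e[i] += X[i, j] * diff
            beta[j] = new

        # additive markers: joint (indicator, effect) update
        ka = 0
        ssa = 0.0
        log_pi = np.log(pi_a / (1.0 - pi_a))
        for j in range(m):
            c = 0.0
            rhs = 0.0
            for i in range(n):
                zij = Z1[i, j]
                if zij != 0.0:
                    c += zij * zij * w[i]
                    rhs += zij * e[i] * w[i]
            rhs += c * a[j]
            C = c + 1.0 / sig_a
            log_odds = log_pi + 0.5 * (np.log(1.0 / sig_a) - np.log(C)) \
                + 0.5 * rhs * rhs / C
            incl = False
            if log_odds > 35.0:
                incl = True
            elif log_odds > -35.0:
                incl = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            if incl:
                new = rhs / C + np.random.normal() / np.sqrt(C)
                ka += 1
                ssa += new * new
            else:
                new = 0.0
            if new != a[j]:
                diff = a[j] - new
                for i in range(n):
                    if Z1[i, j] != 0.0:
                        e[i] += Z1[i, j] * diff
                a[j] = new

        # dominance markers
        kd = 0
        ssd = 0.0
        if use_dom:
            log_pid = np.log(pi_d / (1.0 - pi_d))
            for j in range(m):
                c = 0.0
                rhs = 0.0
                for i in range(n):
                    zij = Z2[i, j]
                    if zij != 0.0:
                        c += zij * zij * w[i]
                        rhs += zij * e[i] * w[i]
                rhs += c * d[j]
                C = c + 1.0 / sig_d
                log_odds = log_pid + 0.5 * (np.log(1.0 / sig_d) - np.log(C)) \
                    + 0.5 * rhs * rhs / C
                incl = False
                if log_odds > 35.0:
                    incl = True
                elif log_odds > -35.0:
                    incl = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
                if incl:
                    new = rhs / C + np.random.normal() / np.sqrt(C)
                    kd += 1
                    ssd += new * new
                else:
                    new = 0.0
                if new != d[j]:
                    diff = d[j] - new
                    for i in range(n):
                        if Z2[i, j] != 0.0:
                            e[i] += Z2[i, j] * diff
                    d[j] = new

        # slab variances (scaled-inv-chi-square)
        if slab_fixed == 0:
            sig_a = (ssa + df0 * S0a) / np.random.chisquare(df0 + ka)
            if use_dom:
                sig_d = (ssd + df0 * S0d) / np.random.chisquare(df0 + kd)
        # pi per term (Beta conjugate)
        if pi_fixed_a < 0.0:
            pi_a = np.random.beta(p0 * pi0 + ka, p0 * (1.0 - pi0) + m - ka)
            pi_a = min(max(pi_a, 1e-6), 1.0 - 1e-6)
        if use_dom:
            pi_d = np.random.beta(p0 * pi0 + kd, p0 * (1.0 - pi0) + m - kd)
            pi_d = min(max(pi_d, 1e-6), 1.0 - 1e-6)
        # per-site residual variances
        for s in range(n_sites):
            ss = 0.0
            for i in range(n):
                if site_idx[i] == s:
                    ss += e[i] * e[i]
            ve[s] = (ss + dfe * Se) / np.random.chisquare(dfe + n_s[s])

        if it >= burn_in and (it - burn_in) % thin == 0:
            traces[kept, 0] = beta[0]
            traces[kept, 1] = sig_a
            traces[kept, 2] = pi_a
            traces[kept, 3] = ka / m
            for s in range(n_sites):
                traces[kept, 4 + s] = ve[s]
            if use_dom:
                traces[kept, 4 + n_sites] = sig_d
                traces[kept, 5 + n_sites] = pi_d
            sum_a += a
            sum_d += d
            for j in range(m):
                if a[j] != 0.0:
                    freq_a[j] += 1.0
                if d[j] != 0.0:
                    freq_d[j] += 1.0
            kept += 1

    return (sum_a / kept, sum_d / kept, freq_a / kept, freq_d / kept,
            traces[:kept])


def gelman_rubin(chains) -> pd.Series:
    """Potential scale reduction factor per monitored parameter.

    ``chains``: sequence (>= 2) of equal-length DataFrames or 2-D arrays of
    post-burn-in samples. PSRF = sqrt(((n-1)/n W + B/n) / W) with W the mean
    within-chain variance and B the between-chain variance of means times n.
    """
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    mats = [np.asarray(c, dtype=float) for c in chains]
    cols = chains[0].columns if isinstance(chains[0], pd.DataFrame) else [
        f"p{j}" for j in range(mats[0].shape[1])
    ]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("chains must have equal length and dimension")
    arr = np.stack(mats)  # (c, n, k)
    c, n, _ = arr.shape
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B = n * arr.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_hat = (n - 1) / n * W + B / n
        psrf = np.sqrt(var_hat / W)
    psrf = np.where(W <= 1e-300, 1.0, psrf)  # degenerate (constant) traces
    # sampling noise can push the ratio slightly below 1; floor it
    return pd.Series(np.maximum(psrf, 1.0), index=cols)


class BayesCPi:
    """scikit-learn-style BayesC-pi estimator.

    ``fit(pheno, genotypes)`` runs ``n_chains`` Gibbs chains on the trait
    named at construction; fitted attributes expose posterior-mean marker
    effects, inclusion probabilities, pi, per-individual GEBV/GEGV and the
    Gelman-Rubin PSRF of the monitored variance parameters.
    """

    def __init__(
        self,
        trait: str = "y",
        effects: str = "a",
        transform: str = "none",
        config: BayesCpiConfig | None = None,
        pi_fixed: float | None = None,
        slab_fixed: tuple | None = None,
    ):
        self.trait = trait
        self.effects = effects
        self.transform = transform
        self.config = config
        self.pi_fixed = pi_fixed
        self.slab_fixed = slab_fixed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "trait": self.trait,
            "effects": self.effects,
            "transform": self.transform,
            "config": self.config,
            "pi_fixed": self.pi_fixed,
            "slab_fixed": self.slab_fixed,
        }

    def set_params(self, **params) -> "BayesCPi":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, pheno: pd.DataFrame, genotypes: GenotypeMatrix) -> "BayesCPi":
        cfg = self.config or BayesCpiConfig()
        if self.effects not in ("a", "ad"):
            raise ValueError("effects must be 'a' or 'ad'")
        data = pheno.dropna(subset=[self.trait])
        ids = data["tree"].astype(str).to_numpy()
        y = _transform_y(data[self.trait].to_numpy(float), self.transform)
        if float(np.var(y)) <= 0:
            raise ValueError("trait has zero variance")
        X, _ = build_fixed_design(data)
        Z1 = genotypes.z1(ids)
        if np.isnan(Z1).any():
            raise ValueError("genotypes contain missing values; impute first")
        Z2 = genotypes.z2(ids)
        use_dom = self.effects == "ad"

        sites = data["site"].astype(str) if "site" in data.columns else pd.Series(
            np.zeros(len(data)), index=data.index
        )
        site_codes, site_levels = pd.factorize(sites)
        vy = float(np.var(y))
        n_terms = 2 if use_dom else 1
        r2_term = cfg.r2 / n_terms
        msx1 = float(np.sum(Z1.var(axis=0)))
        msx2 = float(np.sum(Z2.var(axis=0))) if use_dom else 1.0
        # prior mode of the slab variance from the R^2 heuristic
        S0a = vy * r2_term / max(msx1 * cfg.pi0, 1e-12) * (cfg.df0 + 2) / cfg.df0
        S0d = vy * r2_term / max(msx2 * cfg.pi0, 1e-12) * (cfg.df0 + 2) / cfg.df0
        Se = vy * (1.0 - cfg.r2)
        if self.slab_fixed is not None:
            S0a, S0d = self.slab_fixed
        pi_fixed = -1.0 if self.pi_fixed is None else float(self.pi_fixed)

        trace_names = ["mu", "sigma2_slab_a", "pi_a", "frac_in_a"] + [
            f"sigma2_e[{s}]" for s in site_levels
        ] + (["sigma2_slab_d", "pi_d"] if use_dom else [])

        results = []
        for chain in range(cfg.n_chains):
            seed = (int(cfg.seed) + 100003 * chain) % (2**31 - 1)
            out = _gibbs(
                np.ascontiguousarray(y, dtype=np.float64),
                np.ascontiguousarray(X, dtype=np.float64),
                np.ascontiguousarray(Z1, dtype=np.float64),
                np.ascontiguousarray(Z2, dtype=np.float64),
                np.ascontiguousarray(site_codes, dtype=np.int64),
                len(site_levels),
                cfg.n_iter, cfg.burn_in, cfg.thin,
                cfg.df0, S0a, S0d, cfg.dfe, Se, cfg.p0, cfg.pi0,
                seed, use_dom, pi_fixed,
                1 if self.slab_fixed is not None else 0,
            )
            results.append(out)

        a_hat = np.mean([r[0] for r in results], axis=0)
        d_hat = np.mean([r[1] for r in results], axis=0) if use_dom else None
        inc_a = np.mean([r[2] for r in results], axis=0)
        inc_d = np.mean([r[3] for r in results], axis=0) if use_dom else None
        traces = [pd.DataFrame(r[4], columns=trace_names) for r in results]
        pi_a = float(np.mean([t["pi_a"].mean() for t in traces]))
        pi_d = (
            float(np.mean([t["pi_d"].mean() for t in traces])) if use_dom else None
        )
        if cfg.n_chains >= 2:
            monitored = [c for c in trace_names if c not in ("frac_in_a",)]
            psrf = gelman_rubin([t[monitored] for t in traces])
        else:
            psrf = pd.Series(dtype=float)

        gebv = pd.Series(genotypes.z1() @ a_hat, index=genotypes.ids)
        gegv = (
            pd.Series(genotypes.z1() @ a_hat + genotypes.z2() @ d_hat,
                      index=genotypes.ids)
            if use_dom
            else None
        )
        self.effects_ = MarkerEffects(
            snp_ids=genotypes.snp_ids,
            a_hat=a_hat,
            d_hat=d_hat,
            inclusion_prob_a=inc_a,
            inclusion_prob_d=inc_d,
            pi_hat_a=pi_a,
            pi_hat_d=pi_d,
            gebv=gebv,
            gegv=gegv,
            psrf=psrf,
        traces=traces,
        )
        self.gebv_ = gebv
        self.gegv_ = gegv
        self.psrf_ = psrf
        return self

    def predict(self, genotypes: GenotypeMatrix, kind: str = "gebv") -> pd.Series:
        return predict_from_markers(self.effects_, genotypes, kind=kind)


def fit_bayescpi(
    pheno: pd.DataFrame,
    genotypes: GenotypeMatrix,
    effects: str = "a",
    config: BayesCpiConfig | None = None,
    trait: str = "y",
    transform: str = "none",
) -> MarkerEffects:
    """Functional wrapper over :class:`BayesCPi`."""
    est = BayesCPi(trait=trait, effects=effects, transform=transform, config=config)
    est.fit(pheno, genotypes)
    return est.effects_


def predict_from_markers(
    effects: MarkerEffects, genotypes: GenotypeMatrix, kind: str = "gebv"
) -> pd.Series:
    """GEBV (sum of additive marker effects) or GEGV (plus dominance)."""
    if list(genotypes.snp_ids) != list(effects.snp_ids):
        missing = sorted(set(effects.snp_ids) - set(genotypes.snp_ids))[:5]
        raise ValueError(
            f"marker panels differ (e.g. missing {missing}); cannot predict"
        )
    Z1 = genotypes.z1()
    if np.isnan(Z1).any():
        raise ValueError("genotypes contain missing values; impute first")
    vals = Z1 @ effects.a_hat
    if kind == "gegv":
        if effects.d_hat is None:
            raise ValueError("gegv requested from an additive-only fit")
        vals = vals + genotypes.z2() @ effects.d_hat
    return pd.Series(vals, index=genotypes.ids)
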