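"""SNP quality control and LD-kNN imputation of missing genotypes.

QC filters mirror standard genotyping-array practice: call rate, minor
allele frequency, per-SNP fixation index |Fe| (excess/deficit of
heterozygotes, Fe = 1 - Hobs/Hexp), replicate-discordance error rate, and
Mendelian-segregation checks within full-sib families.

Imputation follows the LD-kNN idea: a missing genotype at SNP s for tree i
is the 1/d^2-weighted modal genotype of the k trees nearest to i, with
distance the mean absolute genotype difference over the l SNPs in highest
r^2 with s (distances offset by +1 so a perfect match keeps finite, maximal
weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "compute_snp_stats",
    "filter_snps",
    "LDkNNImputer",
    "impute_ldknni",
    "imputation_accuracy",
]


@dataclass
class QcThresholds:
    max_missing: float = 0.15
    min_maf: float = 0.01
    max_abs_fe: float = 0.50
    max_error_rate: float = 0.02
    mendel_alpha: float = 0.001
    max_impossible_frac: float = 0.01

    def __post_init__(self):
        for name in (
            "max_missing",
            "min_maf",
            "max_abs_fe",
            "max_error_rate",
            "mendel_alpha",
            "max_impossible_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")


# expected offspring genotype proportions for informative parent crosses
_SEGREGATION = {
    (0, 1): {0: 0.5, 1: 0.5},
    (1, 1): {0: 0.25, 1: 0.5, 2: 0.25},
    (1, 2): {1: 0.5, 2: 0.5},
}
# allowed offspring genotypes for every parental cross
_ALLOWED = {
    (0, 0): {0},
    (0, 1): {0, 1},
    (0, 2): {1},
    (1, 1): {0, 1, 2},
    (1, 2): {1, 2},
    (2, 2): {2},
}


def _mendel_checks(G: np.ndarray, gm: GenotypeMatrix, pedigree: Pedigree):
    """Per-SNP impossible-trio fraction and min Bonferroni-adjusted
    segregation p-value over informative full-sib families."""
    m = G.shape[1]
    geno_ids = set(gm.ids)
    trios = []  # (child_row, sire_row, dam_row) in genotype-matrix indexing
    fam_lab = []
    fam = pedigree.family_codes()
    for i in range(pedigree.n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s < 0 or d < 0:
            continue
        cid, sid, did = pedigree.ids[i], pedigree.ids[s], pedigree.ids[d]
        if cid in geno_ids and sid in geno_ids and did in geno_ids:
            trios.append(
                (gm.index_of([cid])[0], gm.index_of([sid])[0], gm.index_of([did])[0])
            )
            fam_lab.append(fam.loc[cid])
    if not trios:
        return np.zeros(m), np.full(m, np.nan)

    trios = np.asarray(trios)
    child, sire, dam = trios[:, 0], trios[:, 1], trios[:, 2]
    Gc, Gs, Gd = G[child], G[sire], G[dam]
    ok = ~(np.isnan(Gc) | np.isnan(Gs) | np.isnan(Gd))

    impossible = np.zeros(m)
    min_p = np.full(m, np.nan)
    fam_lab = np.asarray(fam_lab)
    families = pd.unique(fam_lab)
    for j in range(m):
        v = ok[:, j]
        if not v.any():
            continue
        lo = np.minimum(Gs[v, j], Gd[v, j]).astype(int)
        hi = np.maximum(Gs[v, j], Gd[v, j]).astype(int)
        c = Gc[v, j].astype(int)
        bad = np.fromiter(
            (ci not in _ALLOWED[(a, b)] for ci, a, b in zip(c, lo, hi)),
            dtype=bool,
            count=len(c),
        )
        impossible[j] = bad.mean()
        pvals = []
        labs = fam_lab[v]
        for f in families:
            rows = labs == f
            if rows.sum() < 5:
                continue
            key = (int(lo[rows][0]), int(hi[rows][0]))
            ratios = _SEGREGATION.get(key)
            if ratios is None or not (lo[rows] == key[0]).all() or not (
                hi[rows] == key[1]
            ).all():
                continue
            cats = sorted(ratios)
            obs = np.array([(c[rows] == g).sum() for g in cats], dtype=float)
            exp = np.array([ratios[g] for g in cats]) * obs.sum()
            pvals.append(sps.chisquare(obs, exp).pvalue)
        if pvals:
            min_p[j] = min(1.0, min(pvals) * len(pvals))  # Bonferroni
    return impossible, min_p


def compute_snp_stats(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    replicates: list[tuple] | None = None,
) -> pd.DataFrame:
    """Per-SNP QC statistics: call rate, MAF, Fe, error rate, Mendel checks.

    ``replicates`` is an optional list of (id_a, id_b) pairs genotyped from
    the same tree; discordant calls over compared calls give the per-SNP
    error rate (NaN when no replicates are supplied).
    """
    G = genotypes.values
    n, m = G.shape
    obs = ~np.isnan(G)
    call_rate = obs.mean(axis=0)

    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0) / 2.0
    maf = np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))

    with np.errstate(invalid="ignore"):
        hobs = np.nanmean(G == 1.0, axis=0)
        hobs = np.where(call_rate > 0, np.nansum((G == 1.0), axis=0) / obs.sum(axis=0), np.nan)
        hexp = 2.0 * p * (1.0 - p)
        fe = np.where(hexp > 0, 1.0 - hobs / hexp, np.nan)

    err = np.full(m, np.nan)
    if replicates:
        ia = genotypes.index_of([a for a, _ in replicates])
        ib = genotypes.index_of([b for _, b in replicates])
        both = obs[ia] & obs[ib]
        with np.errstate(invalid="ignore"):
            disc = (G[ia] != G[ib]) & both
            err = np.where(both.sum(axis=0) > 0, disc.sum(axis=0) / both.sum(axis=0), np.nan)

    if pedigree is not None:
        impossible, mendel_p = _mendel_checks(G, genotypes, pedigree)
    else:
        impossible, mendel_p = np.zeros(m), np.full(m, np.nan)

    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "fe": fe,
            "replicate_error_rate": err,
            "mendel_impossible_frac": impossible,
            "mendel_p": mendel_p,
        }
    )


def filter_snps(stats: pd.DataFrame, thresholds: QcThresholds | None = None):
    """Apply all QC filters; a SNP is retained iff it passes every one.

    Returns ``(retained_ids, attrition)`` where ``attrition`` counts, per
    filter in application order (missingness, MAF, Fe, error rate,
    Mendelian), the SNPs first removed by that filter. The retained set is
    order-invariant; the attrition attribution is not.
    """
    t = thresholds or QcThresholds()
    s = stats
    fail = {
        "missingness": s["call_rate"] < 1.0 - t.max_missing,
        "maf": ~(s["maf"] >= t.min_maf),  # NaN or < min_maf fails (non-segregating)
        "fe": s["fe"].abs() > t.max_abs_fe,  # NaN Fe passes (handled by MAF)
        "error_rate": s["replicate_error_rate"] > t.max_error_rate,
        "mendelian": (s["mendel_p"] < t.mendel_alpha)
        | (s["mendel_impossible_frac"] >= t.max_impossible_frac),
    }
    removed = np.zeros(len(s), dtype=bool)
    attrition = {}
    for name, mask in fail.items():
        mask = mask.fillna(False).to_numpy()
        attrition[name] = int((mask & ~removed).sum())
        removed |= mask
    retained = set(s.loc[~removed, "snp_id"])
    return retained, attrition


# ---------------------------------------------------------------------------
# LD-kNN imputation


class LDkNNImputer:
    """Impute missing 0/1/2 genotypes from LD-informed nearest neighbours.

    Parameters
    ----------
    l : int
        Number of highest-r^2 SNPs used to measure inter-tree distance for
        each target SNP.
    k : int
        Number of nearest neighbours voting on the imputed genotype
        (weights 1/d^2, d offset by +1).

    The transform never alters observed calls and is idempotent on complete
    matrices. SNPs with fewer than ``k`` observed calls fall back to the
    modal genotype (logged).
    """

    def __init__(self, l: int = 30, k: int = 5):
        self.l = l
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"l": self.l, "k": self.k}

    def set_params(self, **params) -> "LDkNNImputer":
        for key, value in params.items():
            if key not in ("l", "k"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "LDkNNImputer":
        if self.l < 1 or self.k < 1:
            raise ValueError("l and k must be >= 1")
        return self

    def _r2_to_targets(self, V, M, targets):
        """r^2 between each target SNP and every SNP, complete pairs only."""
        Vt, Mt = V[:, targets].T, M[:, targets].T  # (b, n)
        N = Mt @ M
        S1 = (Vt * Mt) @ M
        S2 = Mt @ (V * M)
        Sxy = Vt @ V  # V already zero where missing
        Sxx = (Vt**2) @ M
        Syy = Mt @ (V**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = Sxy - S1 * S2 / N
            vx = Sxx - S1**2 / N
            vy = Syy - S2**2 / N
            r2 = cov**2 / (vx * vy)
        r2[~np.isfinite(r2)] = 0.0
        return r2

    def transform(self, X) -> GenotypeMatrix:
        gm = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            ids=[str(i) for i in range(np.asarray(X).shape[0])],
            snp_ids=[str(j) for j in range(np.asarray(X).shape[1])],
            values=np.asarray(X, dtype=float),
        )
        self.fit(gm)
        G = gm.values.copy()
        miss = np.isnan(G)
        if not miss.any():
            return GenotypeMatrix(ids=gm.ids, snp_ids=gm.snp_ids, values=G)

        M = (~miss).astype(np.float64)
        V = np.where(miss, 0.0, G)
        targets = np.where(miss.any(axis=0))[0]
        r2 = self._r2_to_targets(V, M, targets)

        out = G.copy()
        n_fallback = 0
        for row, s in enumerate(targets):
            obs_rows = np.where(~miss[:, s])[0]
            mis_rows = np.where(miss[:, s])[0]
            if len(obs_rows) == 0:
                continue
            if len(obs_rows) < self.k:
                vals, counts = np.unique(G[obs_rows, s], return_counts=True)
                out[mis_rows, s] = vals[np.argmax(counts)]
                n_fallback += 1
                continue
            r2s = r2[row].copy()
            r2s[s] = -1.0  # exclude self
            L = np.argsort(r2s)[::-1][: self.l]

            A, Ma = V[np.ix_(mis_rows, L)], M[np.ix_(mis_rows, L)]
            B, Mb = V[np.ix_(obs_rows, L)], M[np.ix_(obs_rows, L)]
            numer = np.zeros((len(mis_rows), len(obs_rows)))
            for c in range(len(L)):
                valid = np.outer(Ma[:, c], Mb[:, c])
                numer += np.abs(A[:, c, None] - B[None, :, c]) * valid
            counts = Ma @ Mb.T
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(counts > 0, numer / counts, np.inf) + 1.0

            kk = min(self.k, len(obs_rows))
            nbr = np.argpartition(d, kk - 1, axis=1)[:, :kk]
            dk = np.take_along_axis(d, nbr, axis=1)
            with np.errstate(divide="ignore"):
                w = np.where(np.isfinite(dk), 1.0 / dk**2, 0.0)
            gvals = G[obs_rows, s][nbr]  # (n_mis, k)
            votes = np.zeros((len(mis_rows), 3))
            for g in (0, 1, 2):
                votes[:, g] = np.where(gvals == g, w, 0.0).sum(axis=1)
            imputed = np.argmax(votes, axis=1).astype(float)
            # rows with no finite-distance neighbour fall back to the mode
            dead = votes.sum(axis=1) <= 0
            if dead.any():
                vals, counts = np.unique(G[obs_rows, s], return_counts=True)
                imputed[dead] = vals[np.argmax(counts)]
            out[mis_rows, s] = imputed
        if n_fallback:
            log.warning("%d SNPs had < k observed calls; used modal genotype", n_fallback)
        return GenotypeMatrix(ids=gm.ids, snp_ids=gm.snp_ids, values=out)


def impute_ldknni(genotypes: GenotypeMatrix, l: int = 30, k: int = 5) -> GenotypeMatrix:
    """Functional wrapper over :class:`LDkNNImputer`."""
    return LDkNNImputer(l=l, k=k).fit(genotypes).transform(genotypes)


def imputation_accuracy(
    genotypes: GenotypeMatrix,
    n_mask: int = 10000,
    seed: int = 0,
    l: int = 30,
    k: int = 5,
) -> float:
    """Mask observed calls at random, impute, return the fraction recovered."""
    obs = np.argwhere(~genotypes.missing_mask)
    if n_mask <= 0:
        raise ValueError("n_mask must be > 0")
    if n_mask > len(obs):
        raise ValueError(f"n_mask={n_mask} exceeds {len(obs)} observed cells")
    rng = np.random.default_rng(seed)
    pick = obs[rng.choice(len(obs), size=n_mask, replace=False)]
    masked = genotypes.values.copy()
    truth = masked[pick[:, 0], pick[:, 1]].copy()
    masked[pick[:, 0], pick[:, 1]] = np.nan
    gm = GenotypeMatrix(ids=genotypes.ids, snp_ids=genotypes.snp_ids, values=masked)
    imputed = impute_ldknni(gm, l=l, k=k)
    return float(np.mean(imputed.values[pick[:, 0], pick[:, 1]] == truth))
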