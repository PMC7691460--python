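"""Relationship matrices: pedigree A, genomic G (VanRaden) and dominance D.

The additive pedigree matrix A is built by the tabular method. The realized
genomic matrix G centres each marker column by twice its observed allele
frequency and scales by ``2 * sum(p_k * (1 - p_k))``; the dominance matrix D
uses the heterozygosity-coded covariates of the additive/dominance
orthogonal decomposition, ``{-2p^2, 2pq, -2q^2}`` for genotypes ``{0,1,2}``,
scaled by ``sum((2 p_k q_k)^2)``.

Allele frequencies are estimated from all genotyped individuals passed in
(progeny plus genotyped-only trees), matching realized-relationship
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "RelationshipMatrix",
    "pedigree_to_A",
    "vanraden_G",
    "vitezica_D",
    "condition_psd",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relatedness matrix over an ordered set of individuals.

    ``kind`` is one of ``A`` (pedigree additive), ``G`` (genomic additive),
    ``G_Dom`` (genomic dominance) or ``family_I`` (identity over full-sib
    families, the ABLUP dominance structure).
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str
    conditioned: bool = False
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = np.asarray([str(v) for v in self.ids])
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.asarray([self._index[str(v)] for v in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} absent from {self.kind} matrix")

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "A") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=df.index.to_numpy(), values=df.to_numpy(), kind=kind)


def pedigree_to_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Processing individuals parents-first,
    ``A[i, j] = 0.5 * (A[sire(i), j] + A[dam(i), j])`` for j already placed
    and ``A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]``; an unknown parent
    contributes zero relationship and no inbreeding.
    """
    n = pedigree.n
    order = pedigree.topo_order
    pos = np.empty(n, dtype=np.int64)  # individual -> row in processing order
    pos[order] = np.arange(n)
    sire = np.where(pedigree.sire_idx == UNKNOWN, -1, pos[pedigree.sire_idx])
    dam = np.where(pedigree.dam_idx == UNKNOWN, -1, pos[pedigree.dam_idx])
    sire, dam = sire[order], dam[order]

    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)

    inv = np.empty(n, dtype=np.int64)
    inv[pos] = np.arange(n)  # undo reordering
    A = A[np.ix_(pos, pos)]
    return RelationshipMatrix(ids=pedigree.ids, values=A, kind="A")


def _allele_freq(M: np.ndarray) -> np.ndarray:
    if np.isnan(M).any():
        raise ValueError("genotypes contain missing values; impute first")
    return M.mean(axis=0) / 2.0


def vanraden_G(genotypes) -> RelationshipMatrix:
    """Realized additive relationship matrix from 0/1/2 genotypes.

    ``G = W W' / (2 * sum p_k (1 - p_k))`` with ``W`` the genotype matrix
    column-centred by twice the observed allele frequency. Monomorphic
    columns carry no information and are excluded from numerator and
    denominator alike.
    """
    M, ids = _as_matrix(genotypes)
    p = _allele_freq(M)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; G denominator is zero")
    W = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return RelationshipMatrix(ids=ids, values=(W @ W.T) / denom, kind="G")


def vitezica_D(genotypes) -> RelationshipMatrix:
    """Realized dominance relationship matrix.

    Genotypes {0, 1, 2} are recoded per marker to {-2p^2, 2pq, -2q^2}
    (q = 1 - p); ``D = H H' / sum (2 p_k q_k)^2``. The assignment of the two
    homozygote codes is symmetric in p and q up to marker orientation and
    does not change D.
    """
    M, ids = _as_matrix(genotypes)
    p = _allele_freq(M)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; G_Dom denominator is zero")
    Mp, pp = M[:, poly], p[poly]
    q = 1.0 - pp
    H = np.where(Mp == 1, 2.0 * pp * q, np.where(Mp == 0, -2.0 * pp**2, -2.0 * q**2))
    denom = np.sum((2.0 * pp * q) ** 2)
    return RelationshipMatrix(ids=ids, values=(H @ H.T) / denom, kind="G_Dom")


def condition_psd(K: RelationshipMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """Bump the diagonal by ``epsilon`` when the minimum eigenvalue is <= 0.

    Returns the input unchanged (``conditioned=False``) when already
    positive definite. ``epsilon=0`` on a singular matrix raises.
    """
    w_min = float(np.linalg.eigvalsh(K.values)[0])
    if w_min > 0:
        return K
    if epsilon <= 0:
        raise ValueError(
            f"matrix is singular (min eigenvalue {w_min:.3e}) and epsilon={epsilon}"
        )
    values = K.values + np.eye(K.n) * (epsilon + max(0.0, -w_min))
    return RelationshipMatrix(ids=K.ids, values=values, kind=K.kind, conditioned=True)


def family_identity(families: pd.Series) -> RelationshipMatrix:
    """Identity structure over full-sib families (ABLUP dominance term)."""
    fams = pd.unique(families.dropna())
    return RelationshipMatrix(
        ids=np.asarray([str(f) for f in fams]),
        values=np.eye(len(fams)),
        kind="family_I",
    )


def _as_matrix(genotypes):
    """Accept a GenotypeMatrix, DataFrame (rows=individuals) or ndarray."""
    if hasattr(genotypes, "values") and hasattr(genotypes, "ids"):  # GenotypeMatrix
        return np.asarray(genotypes.values, dtype=np.float64), np.asarray(
            genotypes.ids
        )
    if isinstance(genotypes, pd.DataFrame):
        return genotypes.to_numpy(dtype=np.float64), genotypes.index.to_numpy()
    M = np.asarray(genotypes, dtype=np.float64)
    return M, np.asarray([str(i) for i in range(M.shape[0])])
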