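"""Pedigree container.

A pedigree is a directed acyclic parent map: every individual has zero, one
or two known parents, and parents must not descend from their own offspring.
The container validates acyclicity once, caches a topological ordering used
by the tabular-method relationship matrix, and carries the bookkeeping the
rest of the package needs (founder set, full-sib family codes, which progeny
are genotyped-only, i.e. without phenotypes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]

#: sentinel for an unknown parent in the integer-index representation
UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown ids...)."""


class Pedigree:
    """Individuals with sire/dam links, validated as a DAG.

    Parameters
    ----------
    table : pandas.DataFrame
        Must contain columns ``id``, ``sire``, ``dam``. Missing parents are
        encoded as NaN/None/empty string/``"0"``. Optional columns ``sex``,
        ``cohort``, ``family`` and the boolean ``phenotyped`` are preserved.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "sire", "dam"}
        missing = required - set(table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
        table = table.reset_index(drop=True).copy()
        ids = table["id"].astype(str).to_numpy()
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise PedigreeError(
                f"duplicate individual ids: {list(dup[dup > 1].index[:5])}"
            )
        self.table = table
        self._ids = ids
        self._index = {v: i for i, v in enumerate(ids)}
        self.sire_idx = self._parent_indices(table["sire"])
        self.dam_idx = self._parent_indices(table["dam"])
        for i in range(len(ids)):
            if self.sire_idx[i] == i or self.dam_idx[i] == i:
                raise PedigreeError(f"individual {ids[i]} listed as its own parent")
        self.topo_order = self._topological_order()

    def _parent_indices(self, col: pd.Series) -> np.ndarray:
        out = np.full(len(col), UNKNOWN, dtype=np.int64)
        for i, v in enumerate(col):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            s = str(v)
            if s in ("", "0", "nan", "NA", "None"):
                continue
            j = self._index.get(s)
            if j is None:
                raise PedigreeError(f"parent {s!r} not present in pedigree")
            out[i] = j
        return out

    def _topological_order(self) -> np.ndarray:
        """Kahn's algorithm; raises PedigreeError on a cycle."""
        n = self.n
        n_unprocessed_parents = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p != UNKNOWN:
                    n_unprocessed_parents[i] += 1
                    children[p].append(i)
        queue = [i for i in range(n) if n_unprocessed_parents[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                n_unprocessed_parents[c] -= 1
                if n_unprocessed_parents[c] == 0:
                    queue.append(c)
        if len(order) != n:
            bad = [self._ids[i] for i in range(n) if n_unprocessed_parents[i] > 0]
            raise PedigreeError(f"pedigree contains a cycle involving: {bad[:5]}")
        return np.asarray(order, dtype=np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def ids(self) -> np.ndarray:
        return self._ids

    @property
    def n(self) -> int:
        return len(self._ids)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.asarray([self._index[str(v)] for v in ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"unknown individual id {e.args[0]!r}") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx == UNKNOWN) & (self.dam_idx == UNKNOWN)

    @property
    def founders(self) -> np.ndarray:
        return self._ids[self.is_founder]

    def family_codes(self) -> pd.Series:
        """Full-sib family label ``sire|dam`` per individual (NaN for founders).

        Prefers an explicit ``family`` column when the table carries one.
        """
        if "family" in self.table.columns:
            return pd.Series(self.table["family"].to_numpy(), index=self._ids)
        lab = np.full(self.n, None, dtype=object)
        for i in range(self.n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            if s != UNKNOWN and d != UNKNOWN:
                lab[i] = f"{self._ids[s]}|{self._ids[d]}"
        return pd.Series(lab, index=self._ids)

    # -- io ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pedigree(n={self.n}, founders={int(self.is_founder.sum())})"
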