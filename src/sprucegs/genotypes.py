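"""Genotype matrix container: individuals x SNPs coded 0/1/2 with missing.

Genotypes count copies of the minor (rare) allele. Missing calls are NaN in
the float matrix. The container also provides the two incidence codings the
marker models need: Z1 (minor-allele count) and Z2 (heterozygosity
indicator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    ids: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray  # float64, NaN = missing

    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = np.asarray([str(v) for v in self.ids])
        self.snp_ids = np.asarray([str(v) for v in self.snp_ids])
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match id counts")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.values[~ok])[:5]
            raise ValueError(f"genotype values outside {{0,1,2,NaN}}: {bad}")
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.asarray([self._index[str(v)] for v in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} absent from genotype matrix")

    def subset(self, ids=None, snps=None) -> "GenotypeMatrix":
        rows = self.index_of(ids) if ids is not None else np.arange(self.n)
        if snps is not None:
            snp_pos = {s: j for j, s in enumerate(self.snp_ids)}
            cols = np.asarray([snp_pos[str(s)] for s in snps], dtype=np.int64)
        else:
            cols = np.arange(self.m)
        return GenotypeMatrix(
            ids=self.ids[rows],
            snp_ids=self.snp_ids[cols],
            values=self.values[np.ix_(rows, cols)],
        )

    def allele_freq(self) -> np.ndarray:
        """Per-SNP allele frequency of the counted allele, missing excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def z1(self, ids=None) -> np.ndarray:
        """Minor-allele-count incidence (0/1/2)."""
        rows = self.index_of(ids) if ids is not None else np.arange(self.n)
        return self.values[rows]

    def z2(self, ids=None) -> np.ndarray:
        """Heterozygosity-indicator incidence (0 homozygous, 1 heterozygous)."""
        return (self.z1(ids) == 1.0).astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.snp_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            ids=self.ids.copy(), snp_ids=self.snp_ids.copy(), values=self.values.copy()
        )
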