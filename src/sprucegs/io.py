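"""Readers and writers for the interchange formats.

The canonical genotype interchange is a TSV with individuals as rows, a
header of SNP ids, and cells 0/1/2/NA. PLINK ``--recode A`` (RAW) files and
VCF (GT field only, biallelic sites) are import dialects; VCF genotypes are
re-oriented to minor-allele counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
]


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        ids=df.index.astype(str).to_numpy(),
        snp_ids=df.columns.to_numpy(),
        values=df.to_numpy(dtype=float),
    )


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        ids=df["IID"].astype(str).to_numpy(),
        snp_ids=np.asarray([c.rsplit("_", 1)[0] for c in snp_cols]),
        values=df[snp_cols].to_numpy(dtype=float),
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples)
    rows = []
    snp_ids = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        counts = np.select(
            [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        obs = counts[~np.isnan(counts)]
        if len(obs) and obs.mean() / 2.0 > 0.5:  # orient to minor allele
            counts = 2.0 - counts
        rows.append(counts)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_multi:
        log.warning("skipped %d multiallelic VCF records", n_multi)
    return GenotypeMatrix(
        ids=ids, snp_ids=np.asarray(snp_ids), values=np.asarray(rows).T
    )


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV, PLINK-RAW or VCF."""
    readers = {"tsv": _read_tsv, "plink_raw": _read_plink_raw, "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    try:
        return readers[format](path)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"failed to parse {path} as {format}: {exc}") from exc


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tree": str})
    if "tree" not in df.columns:
        raise ValueError("phenotype file must have a 'tree' column")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_csv(path)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_csv(path)
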