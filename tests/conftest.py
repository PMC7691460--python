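"""Shared fixtures: small seeded simulated trials used across test modules."""

import numpy as np
import pandas as pd
import pytest

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.kinship import pedigree_to_A, vanraden_G, vitezica_D
from sprucegs.pedigree import Pedigree
from sprucegs.simdata import SimConfig, TraitSpec, simulate_trial


def two_trait_config(seed=11, ra=0.6, h2=0.5, d2=0.0, **overrides):
    R = [[1.0, ra], [ra, 1.0]]
    n_sites = overrides.pop("n_sites", 3)
    specs = [
        TraitSpec(
            name=f"T{i}",
            mean=10.0,
            h2_target=h2,
            d2_target=d2,
            site_effect_sd=1.0,
            test_effect_sd=0.5,
            residual_sd_by_site=tuple(np.linspace(0.9, 1.1, n_sites)),
            genetic_corr=tuple(R[i]),
        )
        for i in range(2)
    ]
    kwargs = dict(
        n_families=60,
        n_females=30,
        n_males=30,
        progeny_per_family=10,
        n_unphenotyped=40,
        n_sites=n_sites,
        n_snps=600,
        trait_specs=specs,
        seed=seed,
        missing_rate=0.0,
        genotyping_error_rate=0.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_trial():
    """600 phenotyped trees, 2 traits (h2=0.5, ra=0.6), complete genotypes."""
    cfg = two_trait_config()
    ped, geno, pheno, truth = simulate_trial(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "genotypes": geno,
        "phenotypes": pheno,
        "truth": truth,
        "A": pedigree_to_A(ped),
        "G": vanraden_G(geno),
        "D": vitezica_D(geno),
    }


@pytest.fixture(scope="session")
def hwe_genotypes():
    """500 unrelated individuals x 1,000 SNPs in Hardy-Weinberg proportions."""
    rng = np.random.default_rng(7)
    p = rng.uniform(0.1, 0.5, 1000)
    M = rng.binomial(2, p, size=(500, 1000)).astype(float)
    return GenotypeMatrix(
        ids=[f"i{i}" for i in range(500)],
        snp_ids=[f"s{j}" for j in range(1000)],
        values=M,
    )


@pytest.fixture()
def textbook_pedigree():
    """Founders, full sibs, half sibs, and a sire x daughter mating."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["s1", "d1", "d2", "fs1", "fs2", "hs1", "inb"],
                "sire": [None, None, None, "s1", "s1", "s1", "s1"],
                "dam": [None, None, None, "d1", "d1", "d2", "fs1"],
            }
        )
    )
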