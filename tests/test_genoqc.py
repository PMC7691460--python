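"""SNP QC statistics, filtering, and LD-kNN imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprucegs.genoqc import (
    LDkNNImputer,
    QcThresholds,
    compute_snp_stats,
    filter_snps,
    impute_ldknni,
    imputation_accuracy,
)
from sprucegs.genotypes import GenotypeMatrix
from sprucegs.pedigree import Pedigree
from sprucegs.simdata import simulate_genotypes, simulate_pedigree
from tests.conftest import two_trait_config


def _gm(values, ids=None):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix(
        ids=ids or [f"i{i}" for i in range(values.shape[0])],
        snp_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestSnpStats:
    def test_all_heterozygous_fixation_index(self):
        gm = _gm(np.ones((100, 1)))
        stats = compute_snp_stats(gm)
        # Hobs = 1, Hexp = 0.5 -> Fe = -1, fails |Fe| < 0.5
        assert stats.loc[0, "fe"] == pytest.approx(-1.0)
        retained, _ = filter_snps(stats)
        assert retained == set()

    def test_fe_bounded_when_defined(self, small_trial):
        stats = compute_snp_stats(small_trial["genotypes"])
        fe = stats["fe"].dropna()
        assert ((fe >= -1.0 - 1e-9) & (fe <= 1.0 + 1e-9)).all()

    def test_call_rate_matches_masking(self):
        rng = np.random.default_rng(0)
        M = rng.binomial(2, 0.3, size=(500, 40)).astype(float)
        M[rng.random(M.shape) < 0.10] = np.nan
        stats = compute_snp_stats(_gm(M))
        assert stats["call_rate"].mean() == pytest.approx(0.9, abs=0.01)

    def test_monomorphic_snp_reported(self):
        stats = compute_snp_stats(_gm(np.zeros((20, 1))))
        assert stats.loc[0, "maf"] == 0.0
        assert np.isnan(stats.loc[0, "fe"])

    def test_impossible_trio_detected(self):
        ped = Pedigree(
            pd.DataFrame(
                {"id": ["s", "d"] + [f"c{i}" for i in range(6)],
                 "sire": [None, None] + ["s"] * 6,
                 "dam": [None, None] + ["d"] * 6}
            )
        )
        # parents 0 x 0 but one child is 2
        col = np.array([0.0, 0, 0, 0, 0, 0, 0, 2.0])
        stats = compute_snp_stats(_gm(col[:, None], ids=list(ped.ids)), pedigree=ped)
        assert stats.loc[0, "mendel_impossible_frac"] >= 1 / 6

    def test_replicate_error_rate(self):
        M = np.array([[0.0, 1], [0, 2], [1, 1], [1, 1]])
        stats = compute_snp_stats(_gm(M), replicates=[("i0", "i1"), ("i2", "i3")])
        assert stats.loc[0, "replicate_error_rate"] == pytest.approx(0.0)
        assert stats.loc[1, "replicate_error_rate"] == pytest.approx(0.5)


class TestFilters:
    def test_all_monomorphic_zero_retained(self):
        stats = compute_snp_stats(_gm(np.zeros((30, 5))))
        retained, attrition = filter_snps(stats)
        assert retained == set()
        assert attrition["maf"] == 5

    def test_vacuous_thresholds_keep_segregating_snps(self):
        rng = np.random.default_rng(1)
        M = rng.binomial(2, 0.4, size=(200, 30)).astype(float)
        stats = compute_snp_stats(_gm(M))
        thr = QcThresholds(max_missing=1.0, min_maf=0.0, max_abs_fe=1.0,
                           max_error_rate=1.0, mendel_alpha=0.0)
        retained, _ = filter_snps(stats, thr)
        assert len(retained) == 30

    def test_constructed_panel_single_violations(self):
        """5% of SNPs violate exactly one filter each -> 95% retained."""
        rng = np.random.default_rng(2)
        n, m = 400, 100
        M = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        M[:, 0] = np.where(rng.random(n) < 0.5, 0.0, np.nan)  # 50% missing
        M[rng.random(n) < 0.4, 1] = np.nan  # still >15% missing
        M[:, 2] = (rng.random(n) < 0.002).astype(float)  # MAF ~ 0.001
        M[:, 3] = 0.0  # monomorphic
        M[:, 4] = 1.0  # all heterozygous, |Fe| = 1
        stats = compute_snp_stats(_gm(M))
        retained, attrition = filter_snps(stats)
        assert len(retained) == 95
        assert attrition["missingness"] == 2
        assert attrition["maf"] == 2
        assert attrition["fe"] == 1

    def test_retained_set_is_order_invariant(self, small_trial):
        gm = small_trial["genotypes"]
        stats = compute_snp_stats(gm, pedigree=small_trial["pedigree"])
        r1, _ = filter_snps(stats)
        r2, _ = filter_snps(stats.iloc[::-1].reset_index(drop=True))
        assert r1 == r2


class TestImputation:
    def test_identity_on_complete_matrix(self, hwe_genotypes):
        out = impute_ldknni(hwe_genotypes, l=5, k=3)
        assert np.array_equal(out.values, hwe_genotypes.values)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(3)
        M = rng.binomial(2, 0.3, size=(120, 40)).astype(float)
        mask = rng.random(M.shape) < 0.05
        Mm = M.copy()
        Mm[mask] = np.nan
        out = impute_ldknni(_gm(Mm), l=5, k=3)
        assert np.array_equal(out.values[~mask], M[~mask])
        assert not np.isnan(out.values).any()

    def test_perfect_ld_duplicate_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, size=(150, 1)).astype(float)
        noise = rng.binomial(2, 0.4, size=(150, 3)).astype(float)
        M = np.hstack([base, base.copy(), noise])
        M[7, 0] = np.nan  # mask one cell of the duplicated pair
        out = impute_ldknni(_gm(M), l=1, k=5)
        assert out.values[7, 0] == base[7, 0]

    def test_duplicate_column_panel_accuracy_one(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        M = np.hstack([base, base])  # every SNP perfectly duplicated
        # mask cells only in the first copies so each duplicate stays observed
        rows = rng.choice(200, size=50, replace=False)
        cols = rng.integers(0, 5, size=50)
        truth = M[rows, cols].copy()
        M[rows, cols] = np.nan
        out = impute_ldknni(_gm(M), l=1, k=3)
        assert np.array_equal(out.values[rows, cols], truth)

    def test_beats_modal_baseline_on_block_ld_panel(self):
        cfg = two_trait_config(seed=31, n_snps=400, ld_block_size=20,
                              n_families=40, progeny_per_family=8,
                              n_unphenotyped=0)
        ped = simulate_pedigree(cfg)
        gm = simulate_genotypes(ped, cfg)
        rng = np.random.default_rng(6)
        obs = np.argwhere(~np.isnan(gm.values))
        pick = obs[rng.choice(len(obs), size=1000, replace=False)]
        truth = gm.values[pick[:, 0], pick[:, 1]].copy()
        masked = gm.values.copy()
        masked[pick[:, 0], pick[:, 1]] = np.nan
        gmm = _gm(masked)
        out = impute_ldknni(gmm, l=20, k=5)
        acc = np.mean(out.values[pick[:, 0], pick[:, 1]] == truth)
        # modal-genotype baseline per SNP
        modal = np.zeros(gm.m)
        for j in range(gm.m):
            col = masked[:, j]
            col = col[~np.isnan(col)]
            vals, counts = np.unique(col, return_counts=True)
            modal[j] = vals[np.argmax(counts)]
        base_acc = np.mean(modal[pick[:, 1]] == truth)
        assert acc > base_acc

    def test_fallback_when_too_few_observed(self):
        M = np.array(
            [[0.0, 0], [0, 0], [0, 1], [np.nan, 0], [np.nan, 0], [np.nan, 0]]
        )
        out = impute_ldknni(_gm(M), l=1, k=5)  # only 3 observed calls at s0
        assert np.all(out.values[3:, 0] == 0.0)  # modal genotype

    def test_masking_errors(self, hwe_genotypes):
        with pytest.raises(ValueError, match="n_mask"):
            imputation_accuracy(hwe_genotypes, n_mask=0)
        with pytest.raises(ValueError, match="exceeds"):
            imputation_accuracy(hwe_genotypes, n_mask=10**9)

    def test_accuracy_reproducible_and_in_envelope(self, small_trial):
        cfg = two_trait_config(seed=32, missing_rate=0.01, n_snps=300)
        ped = simulate_pedigree(cfg)
        gm = simulate_genotypes(ped, cfg)
        a1 = imputation_accuracy(gm, n_mask=500, seed=11, l=20, k=5)
        a2 = imputation_accuracy(gm, n_mask=500, seed=11, l=20, k=5)
        assert a1 == a2
        assert 0.5 < a1 < 1.0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=1000))
def test_imputer_params_roundtrip(seed):
    imp = LDkNNImputer(l=seed % 40 + 1, k=seed % 7 + 1)
    assert LDkNNImputer(**imp.get_params()).get_params() == imp.get_params()
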