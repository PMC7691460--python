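"""Selection strategies: sizes, gains, constraints, and truth-based signs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprucegs.mixedmodel import fit_univariate
from sprucegs.selection import (
    CandidateSet,
    correlation_breakers,
    expected_gains,
    gain_matrix,
    independent_culling,
    predict_unphenotyped,
    select_top,
    selection_index,
)


@pytest.fixture(scope="module")
def candidates(small_trial):
    """Candidate set from true breeding values (oracle for sign checks)."""
    truth = small_trial["truth"]
    ped = small_trial["pedigree"]
    prog = ped.ids[~ped.is_founder]
    values = truth.true_breeding_values.loc[prog]
    means = pd.Series({"T0": 10.0, "T1": 10.0})
    return CandidateSet(
        values=values, phenotypic_means=means, family_of=ped.family_codes()
    )


class TestSelectTop:
    def test_reference_population_size(self):
        vals = pd.Series(np.arange(1516, dtype=float),
                         index=[f"t{i}" for i in range(1516)])
        assert len(select_top(vals, 0.05)) == 76  # round-half-up of 75.8

    def test_small_population(self):
        vals = pd.Series(np.arange(100, dtype=float))
        assert len(select_top(vals, 0.05)) == 5

    def test_ties_broken_by_stable_id_order(self):
        vals = pd.Series(0.0, index=[f"t{i:04d}" for i in range(100)])
        sel = select_top(vals, 0.05)
        assert sel == [f"t{i:04d}" for i in range(5)]

    def test_empty_and_bad_intensity(self):
        with pytest.raises(ValueError):
            select_top(pd.Series(dtype=float), 0.05)
        with pytest.raises(ValueError):
            select_top(pd.Series([1.0]), 1.5)


class TestExpectedGains:
    def test_selecting_everything_gives_near_zero_gain(self, candidates):
        rep = expected_gains(list(candidates.ids), candidates)
        assert np.abs(rep.gains).max() < 1.0

    def test_positive_correlated_gain_for_positive_ra(self, candidates):
        sel = select_top(candidates.values["T0"], 0.05)
        rep = expected_gains(sel, candidates)
        assert rep.gains["T0"] > 0
        assert rep.gains["T1"] > 0  # simulated ra = +0.6
        assert rep.n_families <= len(sel)

    def test_correlated_loss_for_negative_ra(self):
        from sprucegs.simdata import simulate_trial
        from tests.conftest import two_trait_config

        cfg = two_trait_config(seed=51, ra=-0.4, n_unphenotyped=0)
        ped, geno, pheno, truth = simulate_trial(cfg)
        prog = ped.ids[~ped.is_founder]
        cand = CandidateSet(
            values=truth.true_breeding_values.loc[prog],
            phenotypic_means=pd.Series({"T0": 10.0, "T1": 10.0}),
            family_of=ped.family_codes(),
        )
        rep = expected_gains(select_top(cand.values["T0"], 0.05), cand)
        assert rep.gains["T0"] > 0 > rep.gains["T1"]

    def test_zero_mean_rejected(self, candidates):
        bad = CandidateSet(
            values=candidates.values,
            phenotypic_means=pd.Series({"T0": 0.0, "T1": 10.0}),
            family_of=candidates.family_of,
        )
        with pytest.raises(ValueError, match="T0"):
            expected_gains(list(bad.ids[:5]), bad)


class TestCulling:
    def test_vacuous_constraint_equals_select_top(self, candidates):
        rep = independent_culling(candidates, "T0", [("T1", -np.inf)], 0.05)
        assert set(rep.selected) == set(select_top(candidates.values["T0"], 0.05))

    def test_culling_reduces_primary_gain(self, candidates):
        free = expected_gains(select_top(candidates.values["T0"], 0.05),
                              candidates)
        # cull below the T1 median: binding constraint
        thr = float(candidates.values["T1"].median())
        culled = independent_culling(candidates, "T0", [("T1", thr)], 0.05)
        assert culled.gains["T0"] <= free.gains["T0"] + 1e-12
        assert culled.gains["T1"] >= free.gains["T1"]

    def test_contradictory_constraints_flagged_empty(self, candidates):
        rep = independent_culling(candidates, "T0", [("T1", np.inf)], 0.05)
        assert rep.selected == [] and rep.shortfall

    def test_unknown_trait_rejected(self, candidates):
        with pytest.raises(ValueError, match="unknown trait"):
            independent_culling(candidates, "T0", [("XX", 0.0)], 0.05)


class TestIndex:
    def test_single_trait_index_equals_select_top(self, candidates):
        rep = selection_index(candidates, {"T0": 1.0}, 0.05)
        assert rep.selected == select_top(candidates.values["T0"], 0.05)

    def test_equal_weights_trade_off(self, candidates):
        idx = selection_index(candidates, {"T0": 0.5, "T1": 0.5}, 0.05)
        top0 = expected_gains(select_top(candidates.values["T0"], 0.05), candidates)
        top1 = expected_gains(select_top(candidates.values["T1"], 0.05), candidates)
        assert idx.gains["T0"] > 0 and idx.gains["T1"] > 0
        assert idx.gains["T0"] <= top0.gains["T0"]
        assert idx.gains["T1"] <= top1.gains["T1"]

    def test_perfectly_correlated_traits_match_single_trait(self, candidates):
        vals = candidates.values.copy()
        vals["T1"] = 2.0 * vals["T0"]  # same ranking
        cand = CandidateSet(values=vals, phenotypic_means=candidates.phenotypic_means,
                            family_of=candidates.family_of)
        rep = selection_index(cand, {"T0": 0.5, "T1": 0.5}, 0.05)
        assert rep.selected == select_top(vals["T0"], 0.05)

    def test_zero_variance_trait_rejected(self, candidates):
        vals = candidates.values.copy()
        vals["T1"] = 1.0
        cand = CandidateSet(values=vals, phenotypic_means=candidates.phenotypic_means,
                            family_of=candidates.family_of)
        with pytest.raises(ValueError, match="zero variance"):
            selection_index(cand, {"T0": 0.5, "T1": 0.5}, 0.05)


class TestBreakers:
    def test_all_nonnegative_equals_select_top(self, candidates):
        vals = candidates.values.copy()
        vals["T1"] = vals["T1"] - vals["T1"].min()  # all >= 0
        cand = CandidateSet(values=vals, phenotypic_means=candidates.phenotypic_means,
                            family_of=candidates.family_of)
        rep = correlation_breakers(cand, "T0", "T1", 0.05)
        assert set(rep.selected) == set(select_top(vals["T0"], 0.05))

    def test_breakers_exist_under_negative_correlation(self):
        from sprucegs.simdata import simulate_trial
        from tests.conftest import two_trait_config

        cfg = two_trait_config(seed=52, ra=-0.4, n_unphenotyped=0)
        ped, geno, pheno, truth = simulate_trial(cfg)
        prog = ped.ids[~ped.is_founder]
        cand = CandidateSet(
            values=truth.true_breeding_values.loc[prog],
            phenotypic_means=pd.Series({"T0": 10.0, "T1": 10.0}),
            family_of=ped.family_codes(),
        )
        rep = correlation_breakers(cand, "T0", "T1", 0.05)
        assert rep.gains["T0"] > 0 and rep.gains["T1"] >= 0

    def test_constrained_gain_bounded_by_unconstrained(self, candidates):
        rep = correlation_breakers(candidates, "T0", "T1", 0.05)
        free = expected_gains(select_top(candidates.values["T0"], 0.05), candidates)
        assert rep.gains["T0"] <= free.gains["T0"] + 1e-12


class TestGainMatrix:
    def test_diagonal_dominance(self, candidates):
        gm = gain_matrix(candidates, 0.05)
        for t in candidates.traits:
            assert gm.loc[t, t] >= gm[t].max() - 1e-12


class TestPredictUnphenotyped:
    def test_gblup_covers_genotyped_only_trees(self, small_trial):
        pheno = small_trial["phenotypes"]
        fit = fit_univariate(pheno, small_trial["G"], trait="T0")
        ped = small_trial["pedigree"]
        unphe = ped.table.loc[
            (~ped.is_founder) & (~ped.table["phenotyped"].astype(bool)), "id"
        ].tolist()
        pred = predict_unphenotyped(fit, None, ids=unphe)
        truth = small_trial["truth"].true_breeding_values["T0"].reindex(unphe)
        assert np.corrcoef(pred, truth)[0, 1] > 0.4

    def test_duplicate_genotype_row_gets_equal_gebv(self):
        from sprucegs.genotypes import GenotypeMatrix
        from sprucegs.kinship import condition_psd, vanraden_G

        rng = np.random.default_rng(9)
        n, m = 80, 120
        M = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        M = np.vstack([M, M[0]])  # clone of tree 0, unphenotyped
        gm = GenotypeMatrix(
            ids=[f"i{i}" for i in range(n)] + ["clone0"],
            snp_ids=[f"s{j}" for j in range(m)],
            values=M,
        )
        G = condition_psd(vanraden_G(gm))
        y = 5 + rng.normal(0, 1, n)
        pheno = pd.DataFrame({"tree": gm.ids[:n], "site": "S1", "test": "T1",
                              "age": 20, "y": y})
        fit = fit_univariate(pheno, G, trait="y")
        assert fit.ebv["clone0"] == pytest.approx(fit.ebv["i0"], abs=1e-6)

    def test_missing_candidate_raises(self, small_trial):
        fit = fit_univariate(small_trial["phenotypes"], small_trial["G"],
                             trait="T0")
        with pytest.raises(KeyError, match="absent"):
            predict_unphenotyped(fit, None, ids=["nonexistent"])

    def test_empty_id_list_returns_empty(self, small_trial):
        fit = fit_univariate(small_trial["phenotypes"], small_trial["G"],
                             trait="T0")
        assert len(predict_unphenotyped(fit, None, ids=[])) == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=1, max_value=3000),
    pct=st.floats(min_value=0.01, max_value=0.5),
)
def test_selected_size_is_round_half_up(n, pct):
    vals = pd.Series(np.arange(n, dtype=float))
    size = len(select_top(vals, pct))
    assert size == int(np.floor(pct * n + 0.5))
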