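"""REML mixed models: oracles, plug-in identities, invariances."""

import numpy as np
import pandas as pd
import pytest

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.kinship import RelationshipMatrix, vanraden_G
from sprucegs.mixedmodel import (
    HeritabilityEstimates,
    KinshipBLUP,
    ModelFit,
    VarianceComponents,
    build_fixed_design,
    fit_bivariate,
    fit_univariate,
    heritability,
    information_criteria,
    lrt_variance,
)


def _fake_fit(sigma_a, sigma_d=None, sigma_f=None, sigma_e=(1.0,), loglik=-100.0,
              n_obs=110, rank_x=10, tag="GBLUP-A"):
    k = 1 + (1 if (sigma_d is not None or sigma_f is not None) else 0) + len(sigma_e)
    comp = VarianceComponents(
        sigma2_a=sigma_a,
        sigma2_d=sigma_d,
        sigma2_f=sigma_f,
        sigma2_e_by_site={f"S{i}": v for i, v in enumerate(sigma_e)},
        loglik=loglik,
        ai_cov=np.full((k, k), np.nan),
        param_names=["additive"]
        + (["dominance"] if (sigma_d is not None or sigma_f is not None) else [])
        + [f"residual[S{i}]" for i in range(len(sigma_e))],
    )
    return ModelFit(
        components=comp, beta_hat=pd.Series(dtype=float), ebv=pd.Series(dtype=float),
        dom_blup=None, model_tag=tag, n_obs=n_obs, rank_X=rank_x, converged=True,
        n_iter=1, trait="y", transform="none",
    )


class TestHeritabilityFormulas:
    def test_additive_only_plugin(self):
        h = heritability(_fake_fit(1.0, sigma_e=(1.0,)))
        assert h.h2 == pytest.approx(0.5)
        assert h.H2 == pytest.approx(0.5)

    def test_family_parameterization_plugin(self):
        # sigma_a=0, sigma_f=0.25, mean sigma_e=0.75: d2 = 4*0.25/1 = 1, H2 = 1
        h = heritability(_fake_fit(0.0, sigma_f=0.25, sigma_e=(0.75,),
                                   tag="ABLUP-AD"))
        assert h.d2 == pytest.approx(1.0)
        assert h.H2 == pytest.approx(1.0)

    def test_genomic_dominance_plugin(self):
        h = heritability(_fake_fit(0.4, sigma_d=0.05, sigma_e=(0.55,),
                                   tag="GBLUP-AD"))
        assert h.h2 == pytest.approx(0.40)
        assert h.d2 == pytest.approx(0.05)
        assert h.H2 == pytest.approx(0.45)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability(_fake_fit(0.0, sigma_e=(0.0,)))


class TestInformationCriteria:
    def test_plugin_values(self):
        aic, bic = information_criteria(_fake_fit(1.0, sigma_e=(1.0, 1.0)))
        # loglik=-100, k=3, residual df=100
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200.0 + 3 * np.log(100))

    def test_extra_component_costs_two_aic(self):
        a = information_criteria(_fake_fit(1.0, sigma_e=(1.0,)))[0]
        ad = information_criteria(_fake_fit(1.0, sigma_d=0.1, sigma_e=(1.0,),
                                            tag="GBLUP-AD"))[0]
        assert ad - a == pytest.approx(2.0)


class TestLRT:
    def test_identical_models_give_half(self):
        full = _fake_fit(1.0, sigma_d=0.1, sigma_e=(1.0,), tag="GBLUP-AD")
        red = _fake_fit(1.0, sigma_e=(1.0,))
        stat, p = lrt_variance(full, red)
        assert stat == 0.0
        assert p == pytest.approx(0.5)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="one variance"):
            lrt_variance(_fake_fit(1.0, sigma_e=(1.0,)), _fake_fit(1.0, sigma_e=(1.0,)))


class TestFixedDesign:
    def test_nested_factor_full_rank(self, small_trial):
        pheno = small_trial["phenotypes"]
        X, names = build_fixed_design(pheno)
        assert np.linalg.matrix_rank(X) == X.shape[1]
        assert names[0] == "intercept"
        assert any(n.startswith("site[") for n in names)
        assert "age" in names


class TestRemlOracles:
    def test_matches_anova_intraclass_with_identity_kinship(self):
        """Balanced one-way layout: REML ratio == ANOVA ICC estimator."""
        rng = np.random.default_rng(0)
        g, r = 60, 4
        ids = np.repeat([f"i{i}" for i in range(g)], r)
        y = 10 + np.repeat(rng.normal(0, 1.0, g), r) + rng.normal(0, 1.0, g * r)
        pheno = pd.DataFrame({"tree": ids, "site": "S1", "test": "T1",
                              "age": 20, "y": y})
        K = RelationshipMatrix(ids=[f"i{i}" for i in range(g)],
                               values=np.eye(g), kind="A")
        h2 = heritability(fit_univariate(pheno, K, trait="y")).h2
        df = pd.DataFrame({"g": ids, "y": y})
        msb = r * df.groupby("g")["y"].mean().var(ddof=1)
        msw = df.groupby("g")["y"].var(ddof=1).mean()
        icc = (msb - msw) / (msb + (r - 1) * msw)
        assert abs(h2 - icc) < 0.02

    def test_gblup_equals_ridge_regression_blup(self):
        """G-matrix animal model == ridge marker BLUP at the matched ratio."""
        rng = np.random.default_rng(1)
        n, m = 200, 300
        M = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        gm = GenotypeMatrix(ids=[f"i{i}" for i in range(n)],
                            snp_ids=[f"s{j}" for j in range(m)], values=M)
        G = vanraden_G(gm)
        p = M.mean(0) / 2
        poly = (p > 0) & (p < 1)
        W = M[:, poly] - 2 * p[poly]
        c = 2 * np.sum(p[poly] * (1 - p[poly]))
        u = W @ rng.normal(0, 0.1, W.shape[1])
        y = 3 + u + rng.normal(0, np.sqrt(np.var(u)), n)
        pheno = pd.DataFrame({"tree": gm.ids, "site": "S1", "test": "T1",
                              "age": 20, "y": y})
        fit = fit_univariate(pheno, G, trait="y")
        lam = fit.components.sigma2_e_bar / (fit.components.sigma2_a / c)
        X = np.ones((n, 1))
        q = W.shape[1]
        C = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(q)]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, W.T @ y]))
        assert np.abs(fit.ebv.to_numpy() - W @ sol[1:]).max() < 1e-6

    def test_null_trait_recovers_near_zero_heritability(self, small_trial):
        rng = np.random.default_rng(2)
        pheno = small_trial["phenotypes"].copy()
        pheno["noise"] = rng.normal(0, 1, len(pheno))
        fit = fit_univariate(pheno, small_trial["G"], trait="noise")
        assert heritability(fit).h2 < 0.05


class TestInvariances:
    def test_h2_invariant_to_trait_scaling(self, small_trial):
        pheno = small_trial["phenotypes"].copy()
        G = small_trial["G"]
        h1 = heritability(fit_univariate(pheno, G, trait="T0")).h2
        pheno["T0"] = pheno["T0"] * 37.5
        h2_ = heritability(fit_univariate(pheno, G, trait="T0")).h2
        assert h1 == pytest.approx(h2_, abs=1e-4)

    def test_predictions_invariant_to_row_order(self, small_trial):
        pheno = small_trial["phenotypes"]
        G = small_trial["G"]
        f1 = fit_univariate(pheno, G, trait="T0")
        f2 = fit_univariate(pheno.sample(frac=1.0, random_state=5), G, trait="T0")
        pd.testing.assert_series_equal(f1.ebv, f2.ebv, atol=1e-6, rtol=1e-4)

    def test_sqrt_transform_applied(self, small_trial):
        pheno = small_trial["phenotypes"].copy()
        pheno["sq"] = pheno["T0"] ** 2
        fit_direct = fit_univariate(pheno, small_trial["G"], trait="T0")
        fit_sqrt = fit_univariate(pheno, small_trial["G"], trait="sq",
                                  transform="sqrt")
        # sqrt of the squared trait is |T0|; with T0 >> 0 the fits agree
        assert fit_sqrt.components.sigma2_a == pytest.approx(
            fit_direct.components.sigma2_a, rel=0.05
        )

    def test_estimator_get_set_params(self, small_trial):
        est = KinshipBLUP(small_trial["G"], trait="T0")
        params = est.get_params()
        est2 = KinshipBLUP(**params).set_params(max_iter=55)
        assert est2.max_iter == 55
        with pytest.raises(ValueError):
            est2.set_params(bogus=1)


class TestDominanceModels:
    def test_family_and_genomic_dominance_variants(self, small_trial):
        pheno = small_trial["phenotypes"]
        fam = fit_univariate(pheno, small_trial["A"], dominance="family",
                             trait="T0")
        gen = fit_univariate(pheno, small_trial["G"],
                             dominance=small_trial["D"], trait="T0")
        assert fam.model_tag == "ABLUP-AD"
        assert gen.model_tag == "GBLUP-AD"
        assert fam.components.sigma2_f is not None
        assert gen.components.sigma2_d is not None
        assert gen.egv is not None
        # simulated dominance is zero: both dominance fractions stay small
        assert heritability(fam).d2 < 0.25
        assert heritability(gen).d2 < 0.15

    def test_lrt_power_for_real_additive_signal(self, small_trial):
        from sprucegs.reml import ai_reml

        pheno = small_trial["phenotypes"]
        full = fit_univariate(pheno, small_trial["G"], trait="T0")
        data = pheno.dropna(subset=["T0"])
        X, _ = build_fixed_design(data)
        red = ai_reml(data["T0"].to_numpy(float), X, [],
                      data["site"].to_numpy())
        stat = 2 * (full.loglik - red.loglik)
        from scipy.stats import chi2

        assert 0.5 * chi2.sf(stat, 1) < 0.001


class TestBivariate:
    def test_duplicate_trait_correlations_near_one(self, small_trial):
        pheno = small_trial["phenotypes"].copy()
        pheno["T0b"] = pheno["T0"] + 1e-6 * np.random.default_rng(0).normal(
            size=len(pheno)
        )
        fit = fit_bivariate(pheno, small_trial["G"], traits=("T0", "T0b"))
        assert fit.ra > 0.999
        assert fit.rp > 0.999

    def test_recovers_simulated_additive_correlation(self, small_trial):
        fit = fit_bivariate(small_trial["phenotypes"], small_trial["G"],
                            traits=("T0", "T1"))
        assert 0.4 < fit.ra < 0.8  # target 0.6 at n=600
        assert fit.lrt_p_genetic < 0.01
        assert -1 <= fit.re <= 1 and -1 <= fit.rp <= 1
        # rp formula consistency against a direct correlation of y*
        from sprucegs.crossval import adjusted_phenotypes

        y0 = adjusted_phenotypes(small_trial["phenotypes"], "T0")
        y1 = adjusted_phenotypes(small_trial["phenotypes"], "T1")
        rp_direct = np.corrcoef(y0, y1)[0, 1]
        assert abs(fit.rp - rp_direct) < 0.1

    def test_independent_traits_near_zero(self):
        from sprucegs.simdata import simulate_trial
        from tests.conftest import two_trait_config

        cfg = two_trait_config(seed=41, ra=0.0, n_families=80,
                               progeny_per_family=12, n_unphenotyped=0)
        ped, geno, pheno, truth = simulate_trial(cfg)
        from sprucegs.kinship import vanraden_G

        fit = fit_bivariate(pheno, vanraden_G(geno), traits=("T0", "T1"))
        assert abs(fit.ra) < 0.2

    def test_additive_dominance_bivariate_total_correlation(self, small_trial):
        fit = fit_bivariate(small_trial["phenotypes"], small_trial["G"],
                            traits=("T0", "T1"), dominance=small_trial["D"])
        assert fit.rd is not None
        assert -1 <= fit.rg <= 1
        # with near-zero dominance variance rg stays close to ra
        assert abs(fit.rg - fit.ra) < 0.25
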