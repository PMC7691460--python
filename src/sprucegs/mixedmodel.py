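"""REML/BLUP mixed models for breeding-trial phenotypes.

Univariate model: y = X beta + Z1 a + [Z2 d] + e, with a ~ N(0, sigma_a^2 K)
for K the pedigree (ABLUP) or genomic (GBLUP) relationship matrix, an
optional dominance term — a full-sib family effect sigma_f^2 I for ABLUP or
sigma_d^2 G_Dom for GBLUP — and a heterogeneous residual with one variance
per site. Fixed effects are an overall mean, site, test nested in site, and
tree age as a covariate.

Heritabilities on the individual scale:

    h2 = sigma_a^2 / (sigma_a^2 [+ sigma_d^2] + mean_s sigma_e,s^2)
    d2 = 4 sigma_f^2 / (sigma_a^2 + sigma_f^2 + mean sigma_e^2)   (ABLUP AD)
    d2 = sigma_d^2 / (sigma_a^2 + sigma_d^2 + mean sigma_e^2)     (GBLUP AD)
    H2 = h2 + d2 (GBLUP) or (sigma_a^2 + 4 sigma_f^2) / denom (ABLUP)

with delta-method standard errors from the AI covariance of the variance
components. Bivariate models estimate additive, dominance and residual
correlations (CORGH parameterization: a correlation plus per-trait
variances) and derive total genetic and phenotypic correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .kinship import RelationshipMatrix, family_identity
from .reml import RandomTerm, RemlError, RemlResult, ai_reml

__all__ = [
    "KinshipBLUP",
    "ModelFit",
    "VarianceComponents",
    "HeritabilityEstimates",
    "BivariateFit",
    "build_fixed_design",
    "fit_univariate",
    "fit_bivariate",
    "heritability",
    "lrt_variance",
    "information_criteria",
]


# ---------------------------------------------------------------------------
# fixed-effect design


def build_fixed_design(
    pheno: pd.DataFrame,
    site_col: str = "site",
    test_col: str = "test",
    age_col: str = "age",
):
    """Design matrix: intercept, site, test-within-site, centred age.

    Test-within-site is encoded by dummies for all (site, test) pairs with
    the first test of each site dropped, which keeps the nested factor free
    of columns redundant with site. Any remaining collinear columns are
    dropped by pivoted QR (rank-deficiency warning is the caller's concern).
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    if site_col in pheno.columns and pheno[site_col].nunique() > 1:
        site = pheno[site_col].astype(str)
        levels = sorted(site.unique())
        for lev in levels[1:]:
            cols.append((site == lev).to_numpy(float))
            names.append(f"site[{lev}]")
    if test_col in pheno.columns and site_col in pheno.columns:
        site = pheno[site_col].astype(str)
        test = pheno[test_col].astype(str)
        for lev in sorted(site.unique()):
            tests = sorted(test[site == lev].unique())
            for tl in tests[1:]:
                cols.append(((site == lev) & (test == tl)).to_numpy(float))
                names.append(f"test[{lev}:{tl}]")
    if age_col in pheno.columns and pheno[age_col].nunique() > 1:
        age = pheno[age_col].to_numpy(float)
        cols.append(age - age.mean())
        names.append("age")
    X = np.column_stack(cols)
    # pivoted QR to drop collinear columns
    from scipy.linalg import qr as sqr

    _, R, piv = sqr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-8 * abs(R[0, 0])))
    if rank < X.shape[1]:
        keep_idx = np.sort(piv[:rank])
        X = X[:, keep_idx]
        names = [names[i] for i in keep_idx]
    return X, names


def _transform_y(y: np.ndarray, transform: str) -> np.ndarray:
    if transform in (None, "none"):
        return y
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform requires non-negative trait values")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_d: float | None  # G_Dom-scale dominance variance (GBLUP AD)
    sigma2_f: float | None  # family variance (ABLUP AD)
    sigma2_e_by_site: dict
    loglik: float
    ai_cov: np.ndarray
    param_names: list

    @property
    def sigma2_e_bar(self) -> float:
        return float(np.mean(list(self.sigma2_e_by_site.values())))


@dataclass
class ModelFit:
    components: VarianceComponents
    beta_hat: pd.Series
    ebv: pd.Series
    dom_blup: pd.Series | None
    model_tag: str  # e.g. "GBLUP-AD"
    n_obs: int
    rank_X: int
    converged: bool
    n_iter: int
    trait: str
    transform: str

    @property
    def loglik(self) -> float:
        return self.components.loglik

    @property
    def egv(self) -> pd.Series | None:
        """Additive + dominance BLUP (genetic value); AD fits only."""
        if self.dom_blup is None:
            return None
        return self.ebv.add(self.dom_blup.reindex(self.ebv.index).fillna(0.0))

    @property
    def k_variance_params(self) -> int:
        return len(self.components.param_names)


@dataclass
class HeritabilityEstimates:
    h2: float
    d2: float
    H2: float
    se_h2: float
    se_d2: float
    se_H2: float


# ---------------------------------------------------------------------------
# estimator


class KinshipBLUP:
    """Individual-tree mixed model with a relationship-matrix random effect.

    scikit-learn-style estimator: construct with the covariance structures
    and fit on a phenotype table. ABLUP vs GBLUP is determined by the kind
    of ``kinship`` (pedigree A vs genomic G); passing ``dominance`` turns
    the model into the additive-dominance variant (``"family"`` requests the
    full-sib family-effect parameterization).

    Parameters
    ----------
    kinship : RelationshipMatrix
    dominance : RelationshipMatrix, "family", or None
    trait : str
        Column of the phenotype table to model.
    transform : {"none", "sqrt"}
        Applied to the trait before fitting (right-skewed metabolites).
    """

    def __init__(
        self,
        kinship: RelationshipMatrix,
        dominance=None,
        trait: str = "y",
        transform: str = "none",
        max_iter: int = 200,
        tol: float = 1e-6,
        start=None,
    ):
        self.kinship = kinship
        self.dominance = dominance
        self.trait = trait
        self.transform = transform
        self.max_iter = max_iter
        self.tol = tol
        self.start = start

    def get_params(self, deep: bool = True) -> dict:
        return {
            "kinship": self.kinship,
            "dominance": self.dominance,
            "trait": self.trait,
            "transform": self.transform,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "start": self.start,
        }

    def set_params(self, **params) -> "KinshipBLUP":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, pheno: pd.DataFrame, y=None) -> "KinshipBLUP":
        data = pheno.dropna(subset=[self.trait])
        ids = data["tree"].astype(str).to_numpy()
        yv = _transform_y(data[self.trait].to_numpy(float), self.transform)
        X, xnames = build_fixed_design(data)
        obs_idx = self.kinship.index_of(ids)
        K = self.kinship.values

        terms = [
            RandomTerm(
                name="additive",
                V=K[np.ix_(obs_idx, obs_idx)],
                C_pred=K[:, obs_idx],
                pred_ids=self.kinship.ids,
                q=len(np.unique(obs_idx)),
            )
        ]
        dom = self.dominance
        if isinstance(dom, str) and dom == "family":
            if "family" not in data.columns:
                raise ValueError("family dominance requires a 'family' column")
            dom = family_identity(data["family"])
            dom_levels = data["family"].astype(str).to_numpy()
        elif dom is not None:
            dom_levels = ids
        if dom is not None:
            didx = dom.index_of(dom_levels)
            D = dom.values
            terms.append(
                RandomTerm(
                    name="dominance",
                    V=D[np.ix_(didx, didx)],
                    C_pred=D[:, didx],
                    pred_ids=dom.ids,
                    q=len(np.unique(didx)),
                )
            )

        sites = (
            data["site"].astype(str).to_numpy()
            if "site" in data.columns
            else np.zeros(len(data), dtype=int)
        )
        res = ai_reml(
            yv,
            X,
            terms,
            sites,
            start=self.start,
            max_iter=self.max_iter,
            ll_tol=self.tol,
        )
        self._assemble(res, xnames, dom)
        self.n_obs_ = res.n_obs
        return self

    def _assemble(self, res: RemlResult, xnames, dom):
        names = res.param_names
        theta = dict(zip(names, res.theta))
        has_dom = "dominance" in theta
        family_dom = has_dom and isinstance(dom, RelationshipMatrix) and dom.kind == "family_I"
        self.components_ = VarianceComponents(
            sigma2_a=theta["additive"],
            sigma2_d=(theta["dominance"] if has_dom and not family_dom else None),
            sigma2_f=(theta["dominance"] if family_dom else None),
            sigma2_e_by_site={
                n.split("[", 1)[1][:-1]: v
                for n, v in theta.items()
                if n.startswith("residual[")
            },
            loglik=res.loglik,
            ai_cov=res.ai_cov,
            param_names=names,
        )
        self.beta_ = pd.Series(res.beta, index=xnames)
        self.ebv_ = res.blups["additive"]
        if has_dom:
            dblup = res.blups["dominance"]
            if family_dom:
                # map family BLUPs to individuals through the kinship ids
                self._family_blup_ = dblup
            self.dom_blup_ = dblup
        else:
            self.dom_blup_ = None
        base = "ABLUP" if self.kinship.kind == "A" else "GBLUP"
        self.model_tag_ = f"{base}-{'AD' if has_dom else 'A'}"
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter

    # -- prediction --------------------------------------------------------

    def predict(self, ids, kind: str = "ebv") -> pd.Series:
        """(G)EBV, or (G)EGV for AD fits, for any individuals in the matrix."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("model not fitted")
        ids = [str(v) for v in ids]
        out = self.ebv_.reindex(ids)
        if out.isna().any():
            missing = list(out.index[out.isna()])[:5]
            raise KeyError(f"individuals absent from kinship matrix: {missing}")
        if kind == "egv":
            if self.dom_blup_ is None:
                raise ValueError("egv requested from an additive-only fit")
            d = self.dom_blup_.reindex(ids)
            out = out + d.fillna(0.0)
        return out

    def to_model_fit(self) -> ModelFit:
        dom_blup = self.dom_blup_
        if dom_blup is not None and self.components_.sigma2_f is not None:
            dom_blup = self.dom_blup_  # family-level BLUPs
        return ModelFit(
            components=self.components_,
            beta_hat=self.beta_,
            ebv=self.ebv_,
            dom_blup=dom_blup,
            model_tag=self.model_tag_,
            n_obs=self.n_obs_,
            rank_X=len(self.beta_),
            converged=self.converged_,
            n_iter=self.n_iter_,
            trait=self.trait,
            transform=self.transform,
        )


def fit_univariate(
    pheno: pd.DataFrame,
    K: RelationshipMatrix,
    dominance=None,
    trait: str = "y",
    transform: str = "none",
    **kwargs,
) -> ModelFit:
    """Fit the univariate (additive or additive-dominance) REML model."""
    est = KinshipBLUP(K, dominance=dominance, trait=trait, transform=transform, **kwargs)
    est.fit(pheno)
    fit = est.to_model_fit()
    if isinstance(dominance, str) and dominance == "family":
        # attach individual-level dominance predictions (family BLUP per tree)
        fam = pheno.dropna(subset=[trait]).set_index(
            pheno.dropna(subset=[trait])["tree"].astype(str)
        )["family"]
        ind_dom = fam.map(est.dom_blup_)
        fit.dom_blup = pd.Series(ind_dom.to_numpy(), index=fam.index)
    return fit


# ---------------------------------------------------------------------------
# heritability, LRT, information criteria


def heritability(fit: ModelFit) -> HeritabilityEstimates:
    """Individual-scale h2, d2, H2 with delta-method standard errors."""
    c = fit.components
    theta = np.array(
        [c.sigma2_a]
        + ([c.sigma2_d if c.sigma2_d is not None else c.sigma2_f] if "AD" in fit.model_tag else [])
        + list(c.sigma2_e_by_site.values())
    )
    if theta.sum() <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    ad = "AD" in fit.model_tag
    family = c.sigma2_f is not None
    n_site = len(c.sigma2_e_by_site)

    def ratios(th):
        a = th[0]
        d = th[1] if ad else 0.0
        ebar = np.mean(th[(2 if ad else 1):])
        denom = a + d + ebar
        if family:
            return np.array([a / denom, 4 * d / denom, (a + 4 * d) / denom])
        return np.array([a / denom, d / denom, (a + d) / denom])

    vals = ratios(theta)
    cov = c.ai_cov
    se = np.full(3, np.nan)
    if np.isfinite(cov).all() and cov.shape == (len(theta), len(theta)):
        # numerical gradient of each ratio
        Jg = np.empty((3, len(theta)))
        eps = 1e-6 * np.maximum(np.abs(theta), 1e-8)
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps[j]
            tm[j] -= eps[j]
            Jg[:, j] = (ratios(tp) - ratios(tm)) / (2 * eps[j])
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Jg, cov, Jg), 0.0))
    return HeritabilityEstimates(
        h2=float(vals[0]),
        d2=float(vals[1]),
        H2=float(vals[2]),
        se_h2=float(se[0]),
        se_d2=float(se[1]),
        se_H2=float(se[2]),
    )


def lrt_variance(full: ModelFit, reduced: ModelFit) -> tuple[float, float]:
    """Boundary likelihood-ratio test for one dropped variance component.

    The statistic 2(l_full - l_reduced), floored at zero, is referred to the
    0.5 chi2_0 + 0.5 chi2_1 mixture; the reported p-value is
    0.5 * P(chi2_1 > t). Returns (statistic, p).
    """
    if full.k_variance_params != reduced.k_variance_params + 1:
        raise ValueError("reduced model must drop exactly one variance component")
    if full.n_obs != reduced.n_obs or full.trait != reduced.trait:
        raise ValueError("models were not fitted to the same data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(0.5 * chi2.sf(stat, df=1))


def information_criteria(fit: ModelFit) -> tuple[float, float]:
    """(AIC, BIC) with k = number of variance parameters and residual df."""
    k = fit.k_variance_params
    n_res = fit.n_obs - fit.rank_X
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * np.log(n_res)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# bivariate models


@dataclass
class BivariateFit:
    traits: tuple
    ra: float
    rd: float | None
    re: float
    sigma2_a: tuple
    sigma2_d: tuple | None
    sigma2_e: tuple
    rg: float
    rp: float
    se_ra: float
    lrt_p_genetic: float
    lrt_p_phenotypic: float
    loglik: float
    converged: bool
    model_tag: str


def _corgh(v1, v2, r):
    c = r * np.sqrt(v1 * v2)
    return np.array([[v1, c], [c, v2]])


def fit_bivariate(
    pheno: pd.DataFrame,
    K: RelationshipMatrix,
    traits: tuple,
    dominance=None,
    transforms=("none", "none"),
    max_nfev: int = 4000,
) -> BivariateFit:
    """Bivariate REML with CORGH additive (and dominance) covariance.

    Complete-case trees (both traits observed). The additive-only model
    block-diagonalizes after rotating by the eigenvectors of K and is fitted
    in O(n) per likelihood evaluation; the additive-dominance model uses a
    dense stacked likelihood. Residuals are homogeneous per trait (2x2
    CORGH), correlations start at 0, variances at the univariate estimates.
    """
    t1, t2 = traits
    data = pheno.dropna(subset=[t1, t2]).copy()
    ids = data["tree"].astype(str).to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("bivariate fit expects one record per tree")
    y1 = _transform_y(data[t1].to_numpy(float), transforms[0])
    y2 = _transform_y(data[t2].to_numpy(float), transforms[1])
    X, _ = build_fixed_design(data)
    n, p = X.shape

    s1, s2 = float(np.std(y1)), float(np.std(y2))
    y1s, y2s = y1 / s1, y2 / s2
    Kobs = K.submatrix(ids)

    ad = dominance is not None
    if ad:
        if isinstance(dominance, str) and dominance == "family":
            fam = data["family"].astype(str).to_numpy()
            S_dom = (fam[:, None] == fam[None, :]).astype(float)
            family_dom = True
        else:
            S_dom = dominance.submatrix(ids)
            family_dom = False
    else:
        S_dom, family_dom = None, False

    # ---- likelihood machinery -------------------------------------------
    if not ad:
        lam, U = np.linalg.eigh(Kobs)
        lam = np.maximum(lam, 0.0)
        Y = np.column_stack([U.T @ y1s, U.T @ y2s])
        Xr = U.T @ X

        def negll(par, mask=None):
            par = _apply_mask(par, mask)
            va1, va2, ra, ve1, ve2, re = _unpack_a(par)
            B = lam[:, None, None] * _corgh(va1, va2, ra) + _corgh(ve1, ve2, re)
            det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] ** 2
            if np.any(det <= 0) or np.any(B[:, 0, 0] <= 0):
                return 1e10
            i00 = B[:, 1, 1] / det
            i11 = B[:, 0, 0] / det
            i01 = -B[:, 0, 1] / det
            # X' V^-1 X, X' V^-1 y, y' V^-1 y in the rotated basis
            M = np.zeros((2 * p, 2 * p))
            M[:p, :p] = Xr.T @ (i00[:, None] * Xr)
            M[p:, p:] = Xr.T @ (i11[:, None] * Xr)
            M[:p, p:] = Xr.T @ (i01[:, None] * Xr)
            M[p:, :p] = M[:p, p:].T
            rhs = np.concatenate(
                [
                    Xr.T @ (i00 * Y[:, 0] + i01 * Y[:, 1]),
                    Xr.T @ (i01 * Y[:, 0] + i11 * Y[:, 1]),
                ]
            )
            yVy = float(
                np.sum(i00 * Y[:, 0] ** 2 + 2 * i01 * Y[:, 0] * Y[:, 1] + i11 * Y[:, 1] ** 2)
            )
            try:
                cfm = cho_factor(M, lower=True)
            except np.linalg.LinAlgError:
                return 1e10
            beta = cho_solve(cfm, rhs)
            ldM = 2.0 * np.sum(np.log(np.diag(cfm[0])))
            return 0.5 * (np.sum(np.log(det)) + ldM + yVy - rhs @ beta)

    else:
        I_n = np.eye(n)
        Yst = np.concatenate([y1s, y2s])
        Xb = np.zeros((2 * n, 2 * p))
        Xb[:n, :p] = X
        Xb[n:, p:] = X

        def negll(par, mask=None):
            par = _apply_mask(par, mask)
            va1, va2, ra, vd1, vd2, rd, ve1, ve2, re = _unpack_ad(par)
            V = np.kron(_corgh(va1, va2, ra), Kobs) + np.kron(
                _corgh(vd1, vd2, rd), S_dom
            ) + np.kron(_corgh(ve1, ve2, re), I_n)
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return 1e10
            ViX = cho_solve(cf, Xb)
            Viy = cho_solve(cf, Yst)
            M = Xb.T @ ViX
            try:
                cfm = cho_factor(M, lower=True)
            except np.linalg.LinAlgError:
                return 1e10
            beta = cho_solve(cfm, Xb.T @ Viy)
            ld = 2.0 * np.sum(np.log(np.diag(cf[0])))
            ldM = 2.0 * np.sum(np.log(np.diag(cfm[0])))
            return 0.5 * (ld + ldM + float(Yst @ Viy) - float((Xb.T @ Viy) @ beta))

    # ---- starting values from univariate fits ----------------------------
    def _uni_start(yv, trait):
        d = data.copy()
        d["_y_"] = yv
        f = fit_univariate(d, K, dominance=dominance if ad else None, trait="_y_")
        c = f.components
        vd = c.sigma2_d if c.sigma2_d is not None else c.sigma2_f
        return c.sigma2_a, (vd or 0.0), c.sigma2_e_bar

    a1, d1, e1 = _uni_start(y1s, t1)
    a2, d2_, e2 = _uni_start(y2s, t2)
    lo = 1e-6
    if not ad:
        x0 = np.log(np.maximum([a1, a2, e1, e2], lo))
        x0 = np.array([x0[0], x0[1], 0.0, x0[2], x0[3], 0.0])
    else:
        x0 = np.array(
            [
                np.log(max(a1, lo)),
                np.log(max(a2, lo)),
                0.0,
                np.log(max(d1, lo)),
                np.log(max(d2_, lo)),
                0.0,
                np.log(max(e1, lo)),
                np.log(max(e2, lo)),
                0.0,
            ]
        )

    def _minimize(mask=None):
        res = optimize.minimize(
            negll,
            x0,
            args=(mask,),
            method="Nelder-Mead",
            options={"maxfev": max_nfev, "xatol": 1e-8, "fatol": 1e-10},
        )
        return res

    res = _minimize()
    ll_full = -res.fun
    par = _apply_mask(res.x, None)

    # LRTs against correlation-free reduced models
    gen_mask = [2] if not ad else [2, 5]  # ra [, rd]
    all_mask = gen_mask + ([5] if not ad else [8])
    ll_gen0 = -_minimize(mask=gen_mask).fun
    ll_all0 = -_minimize(mask=all_mask).fun
    p_gen = float(chi2.sf(max(0.0, 2 * (ll_full - ll_gen0)), df=len(gen_mask)))
    p_phe = float(chi2.sf(max(0.0, 2 * (ll_full - ll_all0)), df=len(all_mask)))

    # SE of ra via numerical Hessian on the transformed scale
    se_ra = _se_of_param(negll, res.x, idx=2)

    if not ad:
        va1, va2, ra, ve1, ve2, re = _unpack_a(par)
        vd1 = vd2 = 0.0
        rd = None
    else:
        va1, va2, ra, vd1, vd2, rd, ve1, ve2, re = _unpack_ad(par)
    # back to original trait scales
    va1, vd1, ve1 = va1 * s1**2, vd1 * s1**2, ve1 * s1**2
    va2, vd2, ve2 = va2 * s2**2, vd2 * s2**2, ve2 * s2**2

    # family-variance parameterization: genetic dominance variance is 4 sigma_f^2
    g1 = 4.0 * vd1 if family_dom else vd1
    g2 = 4.0 * vd2 if family_dom else vd2
    rd_eff = rd if rd is not None else 0.0
    rg = (ra * np.sqrt(va1 * va2) + rd_eff * np.sqrt(g1 * g2)) / np.sqrt(
        (va1 + g1) * (va2 + g2)
    )
    rp = (
        ra * np.sqrt(va1 * va2)
        + rd_eff * np.sqrt(vd1 * vd2)
        + re * np.sqrt(ve1 * ve2)
    ) / np.sqrt((va1 + vd1 + ve1) * (va2 + vd2 + ve2))

    base = "ABLUP" if K.kind == "A" else "GBLUP"
    return BivariateFit(
        traits=(t1, t2),
        ra=float(ra),
        rd=None if rd is None else float(rd),
        re=float(re),
        sigma2_a=(va1, va2),
        sigma2_d=None if not ad else (vd1, vd2),
        sigma2_e=(ve1, ve2),
        rg=float(rg),
        rp=float(rp),
        se_ra=se_ra,
        lrt_p_genetic=p_gen,
        lrt_p_phenotypic=p_phe,
        loglik=float(ll_full),
        converged=bool(res.success),
        model_tag=f"{base}-{'AD' if ad else 'A'}",
    )


def _apply_mask(par, mask):
    if mask:
        par = np.array(par, dtype=float)
        par[mask] = 0.0
    return par


def _unpack_a(par):
    return (
        np.exp(par[0]),
        np.exp(par[1]),
        np.tanh(par[2]),
        np.exp(par[3]),
        np.exp(par[4]),
        np.tanh(par[5]),
    )


def _unpack_ad(par):
    return (
        np.exp(par[0]),
        np.exp(par[1]),
        np.tanh(par[2]),
        np.exp(par[3]),
        np.exp(par[4]),
        np.tanh(par[5]),
        np.exp(par[6]),
        np.exp(par[7]),
        np.tanh(par[8]),
    )


def _se_of_param(negll, xopt, idx: int) -> float:
    """Delta-method SE of tanh(x_idx) from a finite-difference Hessian."""
    k = len(xopt)
    h = 1e-4
    H = np.zeros((k, k))
    f0 = negll(xopt)
    for i in range(k):
        for j in range(i, k):
            xpp = xopt.copy(); xpp[i] += h; xpp[j] += h
            xpm = xopt.copy(); xpm[i] += h; xpm[j] -= h
            xmp = xopt.copy(); xmp[i] -= h; xmp[j] += h
            xmm = xopt.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (negll(xpp) - negll(xpm) - negll(xmp) + negll(xmm)) / (
                4 * h * h
            )
    try:
        cov = np.linalg.inv(H)
        var_z = cov[idx, idx]
        if var_z <= 0:
            return float("nan")
        r = np.tanh(xopt[idx])
        return float(np.sqrt(var_z) * (1 - r**2))
    except np.linalg.LinAlgError:
        return float("nan")
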