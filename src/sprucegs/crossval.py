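"""Family-stratified repeated k-fold cross-validation.

The phenotyped trees are split into k folds within each full-sib family
(members shuffled and dealt round-robin), so every fold holds ~1/k of each
family; the split is repeated ``reps`` times for k x reps training fits per
model and trait. Predictive ability (PA) is the Pearson correlation between
the predicted breeding (or genetic) values of the held-out trees and their
fixed-effect-adjusted phenotypes y*. Prediction accuracy (PACC) is reported
three ways: PA / sqrt(h2) (or sqrt(H2)) using the full-data GBLUP
heritability as the reference for every model class, and the correlation of
fold predictions with full-data ABLUP and full-data GBLUP values treated as
pseudo-true breeding values. The pseudo-truth variants are known to run
optimistic; the ratio form is the headline metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayescpi import BayesCpiConfig, fit_bayescpi, predict_from_markers
from .mixedmodel import (
    ModelFit,
    _transform_y,
    build_fixed_design,
    fit_univariate,
    heritability,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "adjusted_phenotypes",
    "run_cv",
    "pacc_from_pa",
]


def pacc_from_pa(pa: float, h2: float) -> float:
    """Prediction accuracy as PA standardized by sqrt(h2) (or sqrt(H2))."""
    if h2 <= 0:
        raise ValueError("reference heritability must be positive")
    return pa / np.sqrt(h2)


@dataclass
class FoldPlan:
    assignments: pd.DataFrame  # columns: tree, rep, fold
    k: int
    reps: int
    seed: int

    def fold_members(self, rep: int, fold: int) -> np.ndarray:
        a = self.assignments
        return a.loc[(a["rep"] == rep) & (a["fold"] == fold), "tree"].to_numpy()


@dataclass
class CVResult:
    per_fold: pd.DataFrame  # model, trait, rep, fold, pa, pacc_* columns
    summary: pd.Series
    failures: list = field(default_factory=list)

    @property
    def n_fits(self) -> int:
        return len(self.per_fold) + len(self.failures)


def make_folds(
    pheno: pd.DataFrame, k: int = 10, reps: int = 10, seed: int = 0
) -> FoldPlan:
    """Family-stratified fold assignment: shuffle each family, deal round-robin."""
    if k < 2:
        raise ValueError("k must be >= 2")
    trees = pheno["tree"].astype(str).to_numpy()
    if k > len(trees):
        raise ValueError(f"k={k} exceeds population size {len(trees)}")
    fams = (
        pheno["family"].astype(str).to_numpy()
        if "family" in pheno.columns
        else np.zeros(len(trees), dtype=int)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        offset = 0
        for fam in pd.unique(fams):
            members = trees[fams == fam]
            members = members[rng.permutation(len(members))]
            for i, t in enumerate(members):
                rows.append((t, rep, (offset + i) % k))
            offset += len(members)  # stagger so small families spread over folds
    return FoldPlan(
        assignments=pd.DataFrame(rows, columns=["tree", "rep", "fold"]),
        k=k,
        reps=reps,
        seed=seed,
    )


def adjusted_phenotypes(
    pheno: pd.DataFrame, trait: str, transform: str = "none"
) -> pd.Series:
    """y*: residuals of the fixed-effects-only fit (mean, site, test, age)."""
    data = pheno.dropna(subset=[trait])
    y = _transform_y(data[trait].to_numpy(float), transform)
    X, _ = build_fixed_design(data)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=data["tree"].astype(str))


def _fit_model(model: str, effects: str, pheno, bundle, trait, transform,
               start=None):
    """One training fit; returns a callable id -> predicted value."""
    if model in ("ablup", "gblup"):
        K = bundle["A"] if model == "ablup" else bundle["G"]
        dom = None
        if effects == "ad":
            dom = "family" if model == "ablup" else bundle["D"]
        fit = fit_univariate(
            pheno, K, dominance=dom, trait=trait, transform=transform, start=start
        )
        values = fit.ebv if effects == "a" else fit.egv
        return fit, values
    if model == "bayescpi":
        cfg = bundle.get("bayescpi_config") or BayesCpiConfig.reduced(
            seed=bundle.get("seed", 0)
        )
        eff = fit_bayescpi(
            pheno, bundle["genotypes"], effects=effects, config=cfg,
            trait=trait, transform=transform,
        )
        values = eff.gebv if effects == "a" else eff.gegv
        return eff, values
    raise ValueError(f"unknown model {model!r}")


def run_cv(
    model: str,
    effects: str,
    pheno: pd.DataFrame,
    bundle: dict,
    plan: FoldPlan,
    trait: str,
    transform: str = "none",
) -> CVResult:
    """Run the k x reps cross-validation for one model class and trait.

    ``bundle`` carries the shared inputs: relationship matrices ``A``,
    ``G`` (and ``D`` for AD fits), ``genotypes`` for marker models, and
    optional ``bayescpi_config``/``seed``. Held-out trees never contribute
    phenotypes to their own prediction; they enter only through their
    relationship-matrix rows or genotypes. Full-data reference fits are
    computed once for the pseudo-truth accuracies and the reference
    heritability.
    """
    data = pheno.dropna(subset=[trait]).copy()
    data["tree"] = data["tree"].astype(str)
    ystar = adjusted_phenotypes(data, trait, transform)

    # full-data references
    full_gblup_a = fit_univariate(data, bundle["G"], trait=trait, transform=transform)
    h2_ref = heritability(full_gblup_a).h2
    if effects == "ad":
        full_gblup_ad = fit_univariate(
            data, bundle["G"], dominance=bundle["D"], trait=trait, transform=transform
        )
        h2_ref = heritability(full_gblup_ad).H2
        ref_gblup = full_gblup_ad.egv
        ref_ablup = fit_univariate(
            data, bundle["A"], dominance="family", trait=trait, transform=transform
        ).egv
    else:
        ref_gblup = full_gblup_a.ebv
        ref_ablup = fit_univariate(
            data, bundle["A"], trait=trait, transform=transform
        ).ebv

    warm = None
    if model in ("ablup", "gblup"):
        K = bundle["A"] if model == "ablup" else bundle["G"]
        dom = None if effects == "a" else ("family" if model == "ablup" else bundle["D"])
        f0 = fit_univariate(data, K, dominance=dom, trait=trait, transform=transform)
        warm = np.array(
            [f0.components.sigma2_a]
            + ([f0.components.sigma2_d or f0.components.sigma2_f] if effects == "ad" else [])
            + list(f0.components.sigma2_e_by_site.values())
        )

    rows = []
    failures = []
    for rep in range(plan.reps):
        for fold in range(plan.k):
            test_ids = plan.fold_members(rep, fold)
            test_ids = np.asarray([t for t in test_ids if t in set(data["tree"])])
            train = data[~data["tree"].isin(test_ids)]
            if len(test_ids) < 3:
                continue
            try:
                _, values = _fit_model(
                    model, effects, train, bundle, trait, transform, start=warm
                )
            except Exception as exc:  # recorded, excluded from means
                failures.append({"rep": rep, "fold": fold, "error": str(exc)})
                continue
            pred = values.reindex(test_ids)
            obs = ystar.reindex(test_ids)
            pa = float(np.corrcoef(pred, obs)[0, 1])
            rows.append(
                {
                    "model": f"{model}-{effects}",
                    "trait": trait,
                    "rep": rep,
                    "fold": fold,
                    "pa": pa,
                    "pacc_h2": pa / np.sqrt(h2_ref) if h2_ref > 0 else np.nan,
                    "pacc_vs_ablup_full": float(
                        np.corrcoef(pred, ref_ablup.reindex(test_ids))[0, 1]
                    ),
                    "pacc_vs_gblup_full": float(
                        np.corrcoef(pred, ref_gblup.reindex(test_ids))[0, 1]
                    ),
                }
            )
    per_fold = pd.DataFrame(rows)
    metrics = ["pa", "pacc_h2", "pacc_vs_ablup_full", "pacc_vs_gblup_full"]
    summary = {}
    for mcol in metrics:
        summary[mcol] = float(per_fold[mcol].mean()) if len(per_fold) else np.nan
        summary[f"se_{mcol}"] = (
            float(per_fold[mcol].std(ddof=1) / np.sqrt(len(per_fold)))
            if len(per_fold) > 1
            else np.nan
        )
    summary["h2_reference"] = h2_ref
    summary["n_fits"] = float(len(per_fold))
    return CVResult(per_fold=per_fold, summary=pd.Series(summary), failures=failures)
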