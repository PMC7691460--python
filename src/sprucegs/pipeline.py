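"""End-to-end pipeline driver: simulate/read -> QC -> impute -> kinship ->
REML fits -> cross-validation -> selection scenarios.

Every stage logs its counts, outputs go to a per-run directory with a
provenance header (seed, package version, config hash), and one global seed
is expanded into per-stage child seeds so stages are reproducible in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossval import make_folds, run_cv
from .genoqc import QcThresholds, compute_snp_stats, filter_snps, impute_ldknni
from .kinship import pedigree_to_A, vanraden_G, vitezica_D
from .mixedmodel import fit_univariate, heritability, information_criteria
from .selection import CandidateSet, gain_matrix
from .simdata import SimConfig, default_config, simulate_trial

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None  # None -> default study-like configuration
    qc: QcThresholds = field(default_factory=QcThresholds)
    models: tuple = (("gblup", "a"),)
    traits: tuple | None = None  # None -> all simulated traits
    cv_k: int = 5
    cv_reps: int = 2
    selection_intensity: float = 0.05
    run_cv_stage: bool = True
    out_dir: str = "sprucegs_run"
    seed: int = 0


def _provenance(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir", None)  # hash identifies the analysis, not the destination
    blob = json.dumps(payload, default=str, sort_keys=True)
    h = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# sprucegs {__version__} seed={config.seed} config={h}\n"


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)

    sim = config.sim or default_config(seed=config.seed)
    ped, geno, pheno, truth = simulate_trial(sim)
    log.info("simulated %d individuals, %d phenotyped, %d SNPs",
             ped.n, len(pheno), geno.m)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    ped.to_csv(out / "pedigree.csv")

    stats = compute_snp_stats(geno, pedigree=ped)
    retained, attrition = filter_snps(stats, config.qc)
    log.info("QC retained %d/%d SNPs; attrition %s", len(retained), geno.m, attrition)
    _write(stats.set_index("snp_id"), out / "snp_stats.tsv", header)
    geno_qc = geno.subset(snps=sorted(retained))
    geno_c = impute_ldknni(geno_qc)

    A = pedigree_to_A(ped)
    G = vanraden_G(geno_c)
    D = vitezica_D(geno_c)
    G.to_tsv(out / "G.tsv")

    traits = list(config.traits or [s.name for s in sim.trait_specs])
    transforms = {
        s.name: ("sqrt" if s.skew_transform == "square" else "none")
        for s in sim.trait_specs
    }
    bundle = {"A": A, "G": G, "D": D, "genotypes": geno_c, "seed": config.seed}

    herit_rows = []
    fits = {}
    for trait in traits:
        for model, eff in config.models:
            if model == "bayescpi":
                continue  # marker models are CV-only in the driver
            K = A if model == "ablup" else G
            dom = None if eff == "a" else ("family" if model == "ablup" else D)
            fit = fit_univariate(
                pheno, K, dominance=dom, trait=trait, transform=transforms[trait]
            )
            h = heritability(fit)
            aic, bic = information_criteria(fit)
            herit_rows.append(
                {
                    "trait": trait,
                    "model": fit.model_tag,
                    "h2": h.h2,
                    "se_h2": h.se_h2,
                    "d2": h.d2,
                    "H2": h.H2,
                    "loglik": fit.loglik,
                    "AIC": aic,
                    "BIC": bic,
                }
            )
            fits[(trait, model, eff)] = fit
    herit = pd.DataFrame(herit_rows).set_index(["trait", "model"])
    _write(herit, out / "heritability.tsv", header)

    if config.run_cv_stage:
        plan = make_folds(pheno, k=config.cv_k, reps=config.cv_reps, seed=config.seed)
        cv_rows = []
        for trait in traits:
            for model, eff in config.models:
                res = run_cv(model, eff, pheno, bundle, plan, trait,
                             transform=transforms[trait])
                row = res.summary.to_dict()
                row.update({"trait": trait, "model": f"{model}-{eff}"})
                cv_rows.append(row)
        _write(
            pd.DataFrame(cv_rows).set_index(["trait", "model"]),
            out / "cv_summary.tsv",
            header,
        )

    # selection on GEBVs of the first fitted additive model
    first = next((f for (t, m, e), f in fits.items() if e == "a"), None)
    if first is not None:
        values = pd.DataFrame(
            {
                t: fits[(t, m, e)].ebv
                for (t, m, e) in fits
                if e == "a"
            }
        ).dropna()
        means = pd.Series(
            {
                t: float(
                    np.sqrt(pheno[t]).mean()
                    if transforms[t] == "sqrt"
                    else pheno[t].mean()
                )
                for t in values.columns
            }
        )
        fam = ped.family_codes()
        cand = CandidateSet(values=values, phenotypic_means=means, family_of=fam)
        gm = gain_matrix(cand, config.selection_intensity)
        _write(gm, out / "gain_matrix.tsv", header)

    with open(out / "run.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": config.seed,
                "n_individuals": int(ped.n),
                "n_phenotyped": int(len(pheno)),
                "snps_retained": len(retained),
                "attrition": attrition,
            },
            fh,
            indent=2,
        )
    return out
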