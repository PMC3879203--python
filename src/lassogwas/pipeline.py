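"""Orchestration: QC -> kinship -> SMMA scan -> top-K -> EM-LASSO ->
permutation threshold -> annotated report, per trait, with seed control.

Per-trait runs are independent: each trait's permutation seed is derived
deterministically from the master seed and the trait name, so removing a
trait from the selection (or reordering traits) changes nothing for the
others, and a run manifest plus the config reproduces everything
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, genio, kinship, lasso, permutation
from .pedigree import Pedigree
from .scan import bonferroni_threshold, estimate_varcomps_null, select_top_k
from .scan import scan as run_scan

log = logging.getLogger("lassogwas")

_DEFAULTS = {
    "maf_min": 0.01,
    "call_rate_min": 0.90,
    "hwe_p_min": 1e-6,
    "hwe_test": "chi2",
    "top_k": 500,
    "a": 1e-6,
    "b": 1e-6,
    "n_perm": 1000,
    "alpha": 0.05,
    "seed": 1,
    "update_varcomps": False,
    "tol": 1e-6,
    "max_iter": 1000,
    "traits": None,   # None = all phenotype columns
    "genes": None,
    "correlations": None,
    "gene_window": 1_000_000,
}

_REQUIRED_PATHS = ["ped", "map", "pedigree", "phenotypes"]


@dataclass
class RunConfig:
    ped: str
    map: str
    pedigree: str
    phenotypes: str
    out_dir: str
    genes: str | None = None
    correlations: str | None = None
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    hwe_test: str = "chi2"
    top_k: int = 500
    a: float = 1e-6
    b: float = 1e-6
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 1
    update_varcomps: bool = False
    tol: float = 1e-6
    max_iter: int = 1000
    traits: list[str] | None = None
    gene_window: int = 1_000_000

    def validate(self, check_paths: bool = True) -> None:
        errors = []
        if check_paths:
            for key in _REQUIRED_PATHS:
                p = getattr(self, key)
                if p is None:
                    errors.append(f"{key}: required input path missing")
                elif not Path(p).exists():
                    errors.append(f"{key}: file not found: {p}")
            for key in ("genes", "correlations"):
                p = getattr(self, key)
                if p is not None and not Path(p).exists():
                    errors.append(f"{key}: file not found: {p}")
        if not (0 <= self.maf_min <= 0.5):
            errors.append("maf_min must lie in [0, 0.5]")
        if not (0 <= self.call_rate_min <= 1):
            errors.append("call_rate_min must lie in [0, 1]")
        if not (0 <= self.hwe_p_min <= 1):
            errors.append("hwe_p_min must lie in [0, 1]")
        if self.hwe_test not in ("chi2", "exact"):
            errors.append("hwe_test must be 'chi2' or 'exact'")
        if self.top_k < 1:
            errors.append("top_k must be >= 1")
        if self.a <= 0 or self.b <= 0:
            errors.append("gamma prior requires a > 0 and b > 0")
        if self.n_perm < 20:
            errors.append("n_perm must be >= 20")
        if not (0 < self.alpha < 1):
            errors.append("alpha must lie in (0, 1)")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config file into a typed, range-checked :class:`RunConfig`.

    Unknown keys are rejected with a per-key message; defaults match the
    pipeline's standard parameterisation (top_k 500, a = b = 1e-6,
    n_perm 1000, alpha 0.05).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(_REQUIRED_PATHS) | {"out_dir"} | set(_DEFAULTS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    missing = [k for k in _REQUIRED_PATHS + ["out_dir"] if k not in raw]
    if missing:
        raise ValueError(f"missing required config keys: {', '.join(missing)}")
    merged = {**_DEFAULTS, **raw}
    cfg = RunConfig(**merged)
    cfg.validate()
    return cfg


def trait_seed(master_seed: int, trait: str) -> int:
    """Deterministic per-trait seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{trait}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


def run_gwas(config: RunConfig) -> dict:
    """Run the full two-step pipeline for every selected trait.

    Writes, under ``config.out_dir``: the QC report, per-trait scan, fit,
    permutation-null and threshold files, significant-SNP report tables and
    a machine-readable run manifest.  Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    G = genio.read_plink_text(config.ped, config.map)
    ped = Pedigree.from_tsv(config.pedigree)
    pheno = genio.read_phenotypes(config.phenotypes)
    traits = config.traits or list(pheno.columns)
    for t in traits:
        if t not in pheno.columns:
            raise ValueError(f"trait {t!r} not in phenotype file")
    ids = [i for i in G.individual_ids if i in pheno.index]
    if len(ids) < len(G.individual_ids):
        log.info("dropping %d genotyped individuals without phenotypes",
                 len(G.individual_ids) - len(ids))
        keep = [k for k, i in enumerate(G.individual_ids) if i in pheno.index]
        G = genio.GenotypeMatrix(ids, G.snps, G.calls[keep])

    G_qc, qc_report = genio.apply_qc(
        G, config.maf_min, config.call_rate_min, config.hwe_p_min,
        hwe_test=config.hwe_test,
    )
    qc_report.reasons.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    log.info("QC: %d/%d SNPs retained", qc_report.n_retained, qc_report.n_input)
    if config.top_k > G_qc.p:
        raise ValueError(
            f"top_k={config.top_k} exceeds the {G_qc.p} SNPs surviving QC"
        )
    X_all = genio.code_genotypes(G_qc)
    R = kinship.build_A(ped).subset(list(G_qc.individual_ids))
    kin = lasso.KinshipFactor(R)
    priors = lasso.LassoPriors(config.a, config.b)
    genes = annotate.read_gene_table(config.genes) if config.genes else None

    manifest: dict = {
        "seed": config.seed,
        "n_individuals": G_qc.n,
        "qc": {
            "n_input": qc_report.n_input,
            "n_retained": qc_report.n_retained,
            "maf_min": config.maf_min,
            "call_rate_min": config.call_rate_min,
            "hwe_p_min": config.hwe_p_min,
        },
        "bonferroni_neglog10": bonferroni_threshold(G_qc.p, config.alpha),
        "top_k": config.top_k,
        "priors": {"a": config.a, "b": config.b},
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "traits": {},
    }
    report_tables: dict[str, pd.DataFrame] = {}
    for trait in traits:
        ts = time.time()
        try:
            y = pheno.loc[G_qc.individual_ids, trait].to_numpy(dtype=float)
            vc = estimate_varcomps_null(y, R)
            scan_res = run_scan(y, X_all, R, vc)
            scan_res.to_frame(G_qc.snps).to_csv(
                out / f"scan_{trait}.tsv", sep="\t", index=False
            )
            top = select_top_k(scan_res, config.top_k)
            X = X_all[:, top]
            fit = lasso.em_lasso_fit(
                y,
                X,
                kin,
                priors,
                init=scan_res.beta[top],
                sigma_g2=vc.sigma_g2,
                sigma_e2=vc.sigma_e2,
                update_varcomps=config.update_varcomps,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            null = permutation.permutation_null(
                y,
                X,
                kin,
                priors,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=trait_seed(config.seed, trait),
                sigma_g2=vc.sigma_g2,
                sigma_e2=vc.sigma_e2,
                update_varcomps=config.update_varcomps,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            hits = permutation.declare_significant(fit, null)

            snps_top = G_qc.snps.iloc[top].reset_index(drop=True)
            pd.DataFrame(
                {
                    "snp_id": snps_top["snp_id"],
                    "chrom": snps_top["chrom"],
                    "bp": snps_top["bp"],
                    "beta": fit.beta,
                    "lambda": fit.lambda_,
                    "snp_var": fit.snp_var,
                    "h2": fit.h2,
                }
            ).to_csv(out / f"fit_{trait}.tsv", sep="\t", index=False)
            (out / f"fit_{trait}.json").write_text(
                json.dumps(
                    {
                        "mu": fit.mu,
                        "sigma_g2": fit.sigma_g2,
                        "sigma_e2": fit.sigma_e2,
                        "n_iter": fit.n_iter,
                        "converged": bool(fit.converged),
                    },
                    indent=2,
                )
            )
            pd.DataFrame(
                {"perm_index": np.arange(null.n_perm), "max_h2": null.max_h2}
            ).to_csv(out / f"null_{trait}.tsv", sep="\t", index=False)
            (out / f"threshold_{trait}.json").write_text(
                json.dumps(
                    {
                        "trait": trait,
                        "alpha": null.alpha,
                        "n_perm": null.n_perm,
                        "threshold": null.threshold,
                        "seed": null.seed,
                    },
                    indent=2,
                )
            )

            rows = []
            for j in hits:
                row = {
                    "snp_id": snps_top["snp_id"].iloc[j],
                    "chrom": snps_top["chrom"].iloc[j],
                    "bp": int(snps_top["bp"].iloc[j]),
                    "gene": "",
                    "distance": np.nan,
                    "h2": fit.h2[j],
                    "threshold": null.threshold,
                }
                if genes is not None:
                    hit = annotate.nearest_gene(
                        row["chrom"], row["bp"], genes, config.gene_window
                    )
                    if hit is not None:
                        row["gene"], row["distance"], _ = hit
                rows.append(row)
            report_tables[trait] = pd.DataFrame(
                rows,
                columns=["snp_id", "chrom", "bp", "gene", "distance", "h2", "threshold"],
            )
            if not rows:
                log.info("trait %s: no significant SNPs", trait)
            manifest["traits"][trait] = {
                "seed": trait_seed(config.seed, trait),
                "sigma_g2_null": vc.sigma_g2,
                "sigma_e2_null": vc.sigma_e2,
                "threshold": null.threshold,
                "n_significant": len(hits),
                "lasso_converged": bool(fit.converged),
                "seconds": round(time.time() - ts, 2),
            }
        except Exception as e:  # keep other traits running
            log.error("trait %s failed: %s", trait, e)
            manifest["traits"][trait] = {"error": str(e)}
    annotate.render_report(report_tables, out)
    manifest["seconds_total"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
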