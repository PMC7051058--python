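"""End-to-end orchestration: simulate -> QC -> transform -> GWIS x2 -> joint.

The pipeline reproduces the two-stage study design on synthetic or
user-supplied data: variant QC per stage, rank-based inverse-normal
transformation of age within each stage, a covariate-adjusted logistic
interaction scan per stage, the discovery/replication filter with the
direction-concordance gate, weighted Z-score joint analysis, and
(optionally) candidate-gene proxy annotation.  Every run writes a
manifest with the configuration hash and seed; identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .annotate import assign_gene_proxy, read_gene_windows
from .errors import ConfigError
from .gwis import (InteractionModelSpec, genomic_lambda, inverse_normal_transform,
                   qq_table, run_gwis)
from .meta import FilterCriteria, run_two_stage
from .qc import QCThresholds, apply_qc, pca_covariates
from .simulate import (SimulationParams, SyntheticCohort, inject_missingness,
                       simulate_two_stage_study)


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    # synthetic-study block (used when no input files are given)
    n_disc: int = 783
    n_rep: int = 538
    n_variants: int = 50
    n_causal: int = 1
    maf: float = 0.49
    beta0: float = -0.32
    betaG: float = 0.17
    betaE: float = 0.97
    betaI: float = -1.0
    miss_rate: float = 0.0
    # optional real-data inputs: per-stage genotype + phenotype paths
    geno_disc: str | None = None
    pheno_disc: str | None = None
    geno_rep: str | None = None
    pheno_rep: str | None = None
    genes_path: str | None = None
    flank: int = 10_000
    use_pcs: bool = False
    qc: QCThresholds = field(default_factory=QCThresholds)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    model: InteractionModelSpec = field(default_factory=InteractionModelSpec)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        kwargs = dict(raw)
        for key, klass in (("qc", QCThresholds), ("criteria", FilterCriteria),
                           ("model", InteractionModelSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_from_files(geno_path: str, pheno_path: str, label: str):
    if not Path(pheno_path).exists():
        raise ConfigError(f"phenotype file not found: {pheno_path}")
    if not Path(geno_path).exists():
        raise ConfigError(f"genotype file not found: {geno_path}")
    gm = iomod.read_vcf(geno_path) if geno_path.endswith(".vcf") else None
    if gm is None:
        raise ConfigError("dosage-TSV stage input requires read_dosage_tsv; pass a .vcf here")
    ph = iomod.read_phenotypes(pheno_path)
    cov = ph[[c for c in ("sex", "bmi", "study") if c in ph.columns]]
    return gm, ph["outcome"].to_numpy(), ph["age"].to_numpy(), cov, label


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full two-stage analysis; returns artifact paths."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: list[dict] = []

    def _save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        iomod.write_table(df, path)
        artifacts[name] = str(path)
        log.append({"artifact": name, "rows": len(df),
                    "elapsed_s": round(time.time() - t0, 3)})

    stages = []
    if config.geno_disc and config.pheno_disc:
        if not (config.geno_rep and config.pheno_rep):
            raise ConfigError("replication genotype/phenotype paths are required "
                              "when discovery files are given")
        stages.append(_stage_from_files(config.geno_disc, config.pheno_disc, "discovery"))
        stages.append(_stage_from_files(config.geno_rep, config.pheno_rep, "replication"))
    else:
        params = SimulationParams(
            beta0=config.beta0, betaG=config.betaG, betaE=config.betaE,
            betaI=config.betaI, maf=config.maf, n_samples=config.n_disc,
            n_variants=config.n_variants, n_causal=config.n_causal, seed=config.seed)
        disc, rep = simulate_two_stage_study(
            params, dataclasses.replace(params, n_samples=config.n_rep,
                                        seed=config.seed + 1))
        for cohort in (disc, rep):
            gm = inject_missingness(cohort.genotypes, config.miss_rate,
                                    cohort.params.seed) if config.miss_rate else cohort.genotypes
            stages.append((gm, cohort.outcome, cohort.age, cohort.covariates,
                           cohort.stage_label))

    sumstats = {}
    for gm, outcome, age, cov, label in stages:
        gm_qc, report = apply_qc(gm, config.qc)
        _save(f"qc_report_{label}.tsv", report.flags)
        pcs = None
        if config.use_pcs:
            pcs, _ = pca_covariates(gm_qc, k=config.model.n_pcs)
        exposure = inverse_normal_transform(age)
        res = run_gwis(genotypes=gm_qc, outcome=outcome, exposure=exposure,
                       covariates=cov, pcs=pcs, spec=config.model)
        _save(f"{label[:4]}.tsv", res)
        sumstats[label] = res
        lam = genomic_lambda(res.loc[res["converged"], "p"].to_numpy())
        (out / f"lambda_{label}.txt").write_text(f"{lam:.6f}\n")
        artifacts[f"lambda_{label}.txt"] = str(out / f"lambda_{label}.txt")
        _save(f"qq_{label}.tsv", qq_table(res.loc[res["converged"], "p"].to_numpy()))

    joint = run_two_stage(sumstats["discovery"], sumstats["replication"], config.criteria)
    _save("joint.tsv", joint)

    if config.genes_path:
        genes = read_gene_windows(config.genes_path, flank=config.flank)
        _save("gene_proxies.tsv", assign_gene_proxy(sumstats["discovery"], genes))

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "log": log,
        "config": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest.json"] = str(out / "manifest.json")
    return artifacts
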