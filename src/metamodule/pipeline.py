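"""End-to-end orchestration with a single config and fixed-seed reproducibility.

Stages: outlier screening -> per-study SAM -> gene-level meta-analysis ->
consensus module detection -> enrichment / candidate selection / GWAS
replication. Every stage writes TSV outputs and the run ends with a
manifest (parameters, seed, versions, per-stage row counts) sufficient to
reconstruct it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_module
from .datatypes import StudyDataset
from .downstream import gene_level_gwas_p, hypergeom_enrich, select_candidates
from .io import (
    read_gmt,
    read_network,
    read_probe_map,
    read_study,
    write_module,
)
from .meta import meta_analyze
from .preprocess import collapse_probes, common_genes, restrict_to_common_genes, screen_outliers
from .sam import sam_test
from .simulate import network_graph

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    studies: list[dict] = field(default_factory=list)  # study_id, expression, phenotype
    network: str = ""
    gene_sets: str = ""  # GMT, optional
    probe_map: str = ""  # optional
    snp_table: str = ""  # optional
    s0: str | float = "auto"
    n_perm: int = 1000
    fdr_bum: float = 0.001
    n_iter: int = 100
    phi: float = 0.5
    resample: str = "bootstrap"
    z_cut: float = 5.0
    alpha: float = 0.05
    screen: bool = True
    solver_method: str = "auto"
    exact_limit: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.studies:
            raise ValueError("config lists no studies")
        for s in self.studies:
            for key in ("expression", "phenotype"):
                if not Path(s[key]).exists():
                    raise FileNotFoundError(f"study file missing: {s[key]}")
        if not self.network or not Path(self.network).exists():
            raise FileNotFoundError(f"network file missing: {self.network}")
        for opt in (self.gene_sets, self.probe_map, self.snp_table):
            if opt and not Path(opt).exists():
                raise FileNotFoundError(f"configured file missing: {opt}")
        if self.n_perm < 1 or self.n_iter < 1:
            raise ValueError("n_perm and n_iter must be >= 1")
        if not 0 < self.fdr_bum < 1 or not 0 < self.phi < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr_bum, phi and alpha must lie in (0, 1)")


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def load_studies(config: PipelineConfig) -> list[StudyDataset]:
    datasets = []
    probe_map = read_probe_map(config.probe_map) if config.probe_map else None
    for s in config.studies:
        ds = read_study(s["expression"], s["phenotype"], s["study_id"],
                        s.get("platform_tag", ""))
        if probe_map:
            ds = StudyDataset(ds.study_id, collapse_probes(ds.matrix, probe_map),
                              ds.groups, ds.platform_tag)
        datasets.append(ds)
    return datasets


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31 - 1))
                   for name in ("sam", "module", "consensus")}

    t0 = _stage("preprocess")
    datasets = load_studies(config)
    removed_all = {}
    if config.screen:
        screened = []
        for ds in datasets:
            ds2, removed = screen_outliers(ds, z_cut=config.z_cut)
            screened.append(ds2)
            removed_all[ds.study_id] = removed
        datasets = screened
    datasets = restrict_to_common_genes(datasets)
    genes = common_genes(datasets)
    manifest["stages"]["preprocess"] = {
        "n_common_genes": len(genes),
        "outliers_removed": removed_all,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("sam")
    sam_rng = np.random.default_rng(stage_seeds["sam"])
    sam_results = {}
    for ds in datasets:
        res, s0_val = sam_test(ds, n_perm=config.n_perm, s0=config.s0,
                               seed=int(sam_rng.integers(2**31 - 1)))
        res.to_csv(outdir / f"sam_{ds.study_id}.tsv", sep="\t", index_label="gene")
        sam_results[ds.study_id] = res
        logger.info("SAM %s: s0=%.4g", ds.study_id, s0_val)
    manifest["stages"]["sam"] = {
        "n_genes": len(genes), "n_perm": config.n_perm,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("meta")
    meta_table = meta_analyze(sam_results, datasets)
    meta_table.to_csv(outdir / "meta_results.tsv", sep="\t")
    manifest["stages"]["meta"] = {
        "n_rows": int(meta_table.shape[0]),
        "n_fisher_q_lt_alpha": int((meta_table["fisher_q"] < config.alpha).sum()),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("consensus_module")
    graph = network_graph(read_network(config.network))
    module = consensus_module(
        datasets, graph,
        n_iter=config.n_iter, fdr=config.fdr_bum, resample=config.resample,
        phi=config.phi, seed=stage_seeds["consensus"], n_perm=config.n_perm,
        s0=config.s0, method=config.solver_method, exact_limit=config.exact_limit,
    )
    write_module(module, outdir, prefix="consensus_module")
    manifest["stages"]["consensus_module"] = {
        "n_nodes": len(module.nodes), "n_edges": len(module.edges),
        "total_score": module.total_score,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("downstream")
    down: dict = {}
    if config.gene_sets and module.nodes:
        sets = read_gmt(config.gene_sets)
        enrich = hypergeom_enrich(set(module.nodes), sets, set(genes))
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        down["n_enriched_sets"] = int((enrich["p_adj"] < config.alpha).sum())
    candidates = select_candidates(meta_table, module, alpha=config.alpha)
    pd.Series(candidates, name="gene").to_csv(outdir / "candidates.tsv",
                                              sep="\t", index=False)
    down["n_candidates"] = len(candidates)
    if config.snp_table and candidates:
        assocs = pd.read_csv(config.snp_table, sep="\t")
        gwas = gene_level_gwas_p(assocs, candidates, alpha=config.alpha)
        gwas.to_csv(outdir / "gwas_replication.tsv", sep="\t", index_label="gene")
        down["n_replicated"] = int(gwas["associated"].sum())
    down["seconds"] = round(time.perf_counter() - t0, 3)
    manifest["stages"]["downstream"] = down

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
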