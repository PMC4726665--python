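"""Plain-text I/O: expression/phenotype TSV, edge lists, SIF, GMT, GraphML, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import GroundTruth, Module, StudyDataset


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotype_tsv(groups: pd.Series, path) -> None:
    df = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy())


def write_study(ds: StudyDataset, outdir, prefix: str | None = None) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or ds.study_id
    expr = outdir / f"{prefix}_expression.tsv"
    pheno = outdir / f"{prefix}_phenotype.tsv"
    write_expression_tsv(ds.matrix, expr)
    write_phenotype_tsv(ds.groups, pheno)
    return expr, pheno


def read_study(expr_path, pheno_path, study_id: str, platform_tag: str = "") -> StudyDataset:
    return StudyDataset(
        study_id=study_id,
        matrix=read_expression_tsv(expr_path),
        groups=read_phenotype_tsv(pheno_path),
        platform_tag=platform_tag,
    )


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def read_sif(path, relation: str | None = None) -> list[tuple[str, str]]:
    """SIF lines: source <relation> target [target ...]."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3:
                continue
            src, rel, targets = parts[0], parts[1], parts[2:]
            if relation is not None and rel != relation:
                continue
            edges.extend((src, t) for t in targets)
    return edges


def read_network(path) -> list[tuple[str, str]]:
    path = Path(path)
    if path.suffix.lower() == ".sif":
        return read_sif(path)
    return read_edge_list(path)


def read_probe_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "deg_genes": sorted(truth.deg_genes),
        "per_gene_true_smd": {g: truth.per_gene_true_smd[g]
                              for g in sorted(truth.per_gene_true_smd)},
        "planted_module_nodes": sorted(truth.planted_module_nodes),
        "planted_module_edges": [list(e) for e in sorted(truth.planted_module_edges)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        deg_genes=set(payload["deg_genes"]),
        per_gene_true_smd=dict(payload["per_gene_true_smd"]),
        planted_module_nodes=set(payload["planted_module_nodes"]),
        planted_module_edges={tuple(e) for e in payload["planted_module_edges"]},
    )


def write_module(module: Module, outdir, prefix: str = "module") -> tuple[Path, Path]:
    """Module as GraphML plus a TSV of (gene, frequency)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = nx.Graph()
    g.add_nodes_from(sorted(module.nodes))
    g.add_edges_from(sorted(module.edges))
    for v in g.nodes:
        if module.node_freq:
            g.nodes[v]["frequency"] = float(module.node_freq.get(v, 0.0))
    graphml = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, graphml)
    tsv = outdir / f"{prefix}_nodes.tsv"
    with open(tsv, "w") as fh:
        fh.write("gene\tfrequency\n")
        for v in sorted(module.nodes):
            freq = module.node_freq.get(v, "") if module.node_freq else ""
            fh.write(f"{v}\t{freq}\n")
    return graphml, tsv
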