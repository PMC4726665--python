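"""Synthetic multi-study expression data with a planted differential module.

Emulates the setting of a multi-cohort two-group (high vs low phenotype)
microarray meta-analysis: k studies of unequal size, a shared gene universe
(optionally with platform-specific dropout), planted differentially
expressed genes whose standardized mean differences vary between studies,
and a scale-free interaction network containing a connected planted module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GroundTruth, StudyDataset, canonical_edge

logger = logging.getLogger(__name__)

# Log2-scale microarray baseline: per-gene mean ~ N(7, 1.5^2), within-group
# SD ~ U(0.3, 1.0) — a realistic post-normalization dynamic range.
BASELINE_MEAN = 7.0
BASELINE_MEAN_SD = 1.5
WITHIN_SD_LOW = 0.3
WITHIN_SD_HIGH = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated meta-analysis.

    ``n_high``/``n_low`` may be single ints (shared by all studies) or lists
    of length ``k_studies``. Effect sizes of planted DEGs are drawn with
    magnitude uniform in ``smd_range`` and random sign, then perturbed per
    study with variance ``heterogeneity_tau2`` on the SMD scale.
    """

    k_studies: int = 6
    n_high: int | list[int] = field(default_factory=lambda: [40, 14, 10, 45, 10, 10])
    n_low: int | list[int] = field(default_factory=lambda: [40, 12, 9, 39, 10, 10])
    n_genes: int = 2000
    deg_fraction: float = 0.02
    smd_range: tuple[float, float] = (0.4, 0.8)
    heterogeneity_tau2: float = 0.02
    network_nodes: int = 500
    network_attach: int = 2
    planted_module_size: int = 12
    seed: int = 0
    two_platform_dropout: bool = False

    def __post_init__(self) -> None:
        if self.k_studies < 1 or self.n_genes < 1 or self.network_nodes < 1:
            raise ValueError("counts must be >= 1")
        if isinstance(self.n_high, int):
            self.n_high = [self.n_high] * self.k_studies
        if isinstance(self.n_low, int):
            self.n_low = [self.n_low] * self.k_studies
        if len(self.n_high) != self.k_studies or len(self.n_low) != self.k_studies:
            raise ValueError("n_high/n_low must have length k_studies")
        if any(n < 2 for n in list(self.n_high) + list(self.n_low)):
            raise ValueError("each group needs >= 2 samples (pooled SD undefined below that)")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must be in [0, 1]")
        lo, hi = self.smd_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError("smd_range must be finite with low <= high")
        if self.heterogeneity_tau2 < 0:
            raise ValueError("heterogeneity_tau2 must be >= 0")
        if self.planted_module_size < 1 or self.planted_module_size > self.network_nodes:
            raise ValueError("planted_module_size must be in [1, network_nodes]")
        if self.network_nodes > self.n_genes:
            raise ValueError("network_nodes cannot exceed n_genes (nodes are gene IDs)")
        if self.network_attach < 1 or self.network_attach >= self.network_nodes:
            raise ValueError("network_attach must be in [1, network_nodes)")

    @property
    def n_deg(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def simulate_studies(config: SimulationConfig) -> tuple[list[StudyDataset], GroundTruth]:
    """Generate k two-group expression studies plus the planted ground truth.

    Non-DEG genes have identical group means (baseline + noise). A DEG g in
    study i has group mean difference ``smd_{g,i} * sigma_{g,i}`` where
    ``smd_{g,i} = SMD_g + N(0, tau^2)``. Pure function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)

    n_deg = config.n_deg
    if config.deg_fraction > 0 and n_deg < config.planted_module_size:
        raise ValueError(
            f"deg_fraction yields {n_deg} DEGs but planted_module_size is "
            f"{config.planted_module_size}; planted nodes must all be DEGs"
        )

    if n_deg == 0:
        deg_genes: list[str] = []
        planted: list[str] = []
    else:
        deg_genes = sorted(rng.choice(genes, size=n_deg, replace=False))
        planted = sorted(rng.choice(deg_genes, size=config.planted_module_size, replace=False))

    smd_lo, smd_hi = config.smd_range
    true_smd = dict(
        zip(
            deg_genes,
            rng.uniform(smd_lo, smd_hi, size=n_deg) * rng.choice([-1.0, 1.0], size=n_deg),
        )
    )

    mu = rng.normal(BASELINE_MEAN, BASELINE_MEAN_SD, size=config.n_genes)
    deg_idx = np.array([genes.index(g) for g in deg_genes], dtype=int)
    base_smd = np.array([true_smd[g] for g in deg_genes])
    tau = float(np.sqrt(config.heterogeneity_tau2))

    dropout_sets: list[set[str]] = [set(), set()]
    if config.two_platform_dropout:
        n_drop = config.n_genes // 10
        dropped = rng.choice(genes, size=2 * n_drop, replace=False)
        dropout_sets = [set(dropped[:n_drop]), set(dropped[n_drop:])]

    datasets = []
    for i in range(config.k_studies):
        n1, n0 = config.n_high[i], config.n_low[i]
        sigma = rng.uniform(WITHIN_SD_LOW, WITHIN_SD_HIGH, size=config.n_genes)
        study_smd = base_smd + rng.normal(0.0, tau, size=n_deg) if n_deg else base_smd
        delta = np.zeros(config.n_genes)
        if n_deg:
            delta[deg_idx] = study_smd * sigma[deg_idx]

        mean_high = mu + delta / 2.0
        mean_low = mu - delta / 2.0
        x_high = mean_high[:, None] + sigma[:, None] * rng.standard_normal((config.n_genes, n1))
        x_low = mean_low[:, None] + sigma[:, None] * rng.standard_normal((config.n_genes, n0))

        study_id = f"study{i + 1}"
        cols = [f"{study_id}_H{j:03d}" for j in range(n1)] + [
            f"{study_id}_L{j:03d}" for j in range(n0)
        ]
        matrix = pd.DataFrame(np.hstack([x_high, x_low]), index=genes, columns=cols)
        groups = pd.Series(["high"] * n1 + ["low"] * n0, index=cols)

        platform = "simPlatformA" if i % 2 == 0 else "simPlatformB"
        drop = dropout_sets[i % 2]
        if drop:
            matrix = matrix.loc[[g for g in genes if g not in drop]]
        datasets.append(
            StudyDataset(study_id=study_id, matrix=matrix, groups=groups, platform_tag=platform)
        )

    truth = GroundTruth(
        deg_genes=set(deg_genes),
        per_gene_true_smd=true_smd,
        planted_module_nodes=set(planted),
    )
    return datasets, truth


def simulate_network(config: SimulationConfig, truth: GroundTruth) -> list[tuple[str, str]]:
    """Scale-free (preferential-attachment) network whose nodes are gene IDs.

    The planted module's genes are placed on a connected subgraph (the first
    ``planted_module_size`` nodes of a BFS from a random vertex of the
    Barabási–Albert graph), so connectivity holds by construction without
    adding edges. Updates ``truth.planted_module_edges`` with the induced
    edges and returns the undirected edge list.
    """
    rng = np.random.default_rng([config.seed, 1])
    ba_seed = int(rng.integers(2**31 - 1))
    graph = nx.barabasi_albert_graph(config.network_nodes, config.network_attach, seed=ba_seed)

    planted = sorted(truth.planted_module_nodes)
    genes = gene_ids(config.n_genes)
    others = [g for g in genes if g not in truth.planted_module_nodes]
    n_other = config.network_nodes - len(planted)
    other_nodes = sorted(rng.choice(others, size=n_other, replace=False))

    if planted:
        root = int(rng.integers(config.network_nodes))
        bfs_order = [root] + [v for _, v in nx.bfs_edges(graph, root)]
        module_ints = bfs_order[: len(planted)]
    else:
        module_ints = []
    remaining_ints = [v for v in graph.nodes if v not in set(module_ints)]
    mapping = dict(zip(module_ints, planted))
    perm = rng.permutation(len(remaining_ints))
    mapping.update({v: other_nodes[j] for v, j in zip(remaining_ints, perm)})

    relabeled = nx.relabel_nodes(graph, mapping)
    edges = sorted(canonical_edge(u, v) for u, v in relabeled.edges)
    truth.planted_module_edges = {
        canonical_edge(u, v)
        for u, v in relabeled.edges
        if u in truth.planted_module_nodes and v in truth.planted_module_nodes
    }
    return edges


def network_graph(edges: list[tuple[str, str]]) -> nx.Graph:
    """Undirected simple graph from an edge list, dropping any self-loops."""
    graph = nx.Graph()
    graph.add_edges_from((u, v) for u, v in edges if u != v)
    return graph
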