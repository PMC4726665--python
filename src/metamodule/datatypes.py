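"""Shared containers for the meta-analysis pipeline.

Expression matrices are pandas DataFrames (rows = gene or probe IDs,
columns = sample IDs); group labels are a pandas Series mapping sample ID
to ``"high"`` or ``"low"``. Networks are undirected :mod:`networkx` graphs
whose node IDs are gene symbols shared with the expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

GROUP_HIGH = "high"
GROUP_LOW = "low"
VALID_GROUPS = frozenset({GROUP_HIGH, GROUP_LOW})


@dataclass
class StudyDataset:
    """One study's gene-by-sample log2 expression matrix with binary phenotype labels."""

    study_id: str
    matrix: pd.DataFrame
    groups: pd.Series
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"{self.study_id}: samples without group labels: {missing[:5]}")
        bad = set(self.groups.unique()) - VALID_GROUPS
        if bad:
            raise ValueError(f"{self.study_id}: unknown group labels {sorted(bad)}")
        if not self.matrix.index.is_unique:
            raise ValueError(f"{self.study_id}: gene IDs are not unique")
        for g in (GROUP_HIGH, GROUP_LOW):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"{self.study_id}: group '{g}' has fewer than 2 samples")

    @property
    def high_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_HIGH])

    @property
    def low_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_LOW])

    @property
    def n_high(self) -> int:
        return int((self.groups == GROUP_HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.groups == GROUP_LOW).sum())

    def subset_samples(self, sample_ids: list[str]) -> "StudyDataset":
        return StudyDataset(
            study_id=self.study_id,
            matrix=self.matrix.loc[:, sample_ids],
            groups=self.groups.loc[sample_ids],
            platform_tag=self.platform_tag,
        )


@dataclass
class GroundTruth:
    """Planted signal of a simulation: which genes are DEGs and where the module sits."""

    deg_genes: set[str]
    per_gene_true_smd: dict[str, float]
    planted_module_nodes: set[str]
    planted_module_edges: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class BumFit:
    """Beta-uniform mixture fit to a p-value distribution.

    Density ``f(p) = lambda + (1 - lambda) * a * p**(a - 1)`` on (0, 1];
    the uniform component models null genes, the decreasing beta component
    (``a < 1``) models signal.
    """

    lam: float
    a: float
    log_lik: float
    n_pvalues: int

    @property
    def pi0(self) -> float:
        """Upper bound on the noise mass: density value at p = 1."""
        return self.lam + (1.0 - self.lam) * self.a


@dataclass
class ScoredNetwork:
    """Undirected simple graph whose nodes carry additive BUM-derived scores."""

    graph: nx.Graph
    fdr_level: float

    def score(self, node) -> float:
        return float(self.graph.nodes[node]["score"])


@dataclass
class Module:
    """A connected subnetwork: node set, induced edges and summed node score."""

    nodes: set
    edges: set
    total_score: float
    node_freq: dict = field(default_factory=dict)
    edge_freq: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nodes)


def canonical_edge(u, v) -> tuple:
    """Unordered edge as a sorted tuple, so edge sets compare reliably."""
    return (u, v) if u <= v else (v, u)
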