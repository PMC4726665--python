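"""Consensus module detection by resampling.

One detection pass runs per-study SAM, Fisher combination, a BUM fit of the
combined p-values, node scoring at a restrictive FDR, and the
maximum-scoring subnetwork search. The consensus procedure repeats this on
within-study resampled data (stratified bootstrap by default), counts how
often each node and edge appears across the resulting modules, converts
node frequencies into consensus scores (frequency - phi) and re-solves, so
only reproducibly selected regions of the network survive.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .bum import fit_bum, score_pvalues
from .datatypes import Module, ScoredNetwork, StudyDataset, canonical_edge
from .meta import fisher_combine_matrix
from .preprocess import common_genes
from .sam import sam_test
from .subnetwork import EXACT_LIMIT_DEFAULT, largest_component, max_scoring_subnetwork

logger = logging.getLogger(__name__)

RESAMPLE_MODES = ("bootstrap", "permute", "none")


def resample_dataset(ds: StudyDataset, mode: str, rng: np.random.Generator) -> StudyDataset:
    """Within-study resample preserving group sizes.

    ``bootstrap``: sample with replacement within each phenotype group
    (signal-preserving). ``permute``: shuffle the group labels (signal-
    nullifying; useful for null calibration). ``none``: identity.
    """
    if mode == "none":
        return ds
    if mode == "bootstrap":
        cols: list[str] = []
        for grp in ("high", "low"):
            ids = [s for s in ds.matrix.columns if ds.groups[s] == grp]
            cols.extend(rng.choice(ids, size=len(ids), replace=True))
        mat = ds.matrix.loc[:, cols].copy()
        new_names = [f"{c}__r{j}" for j, c in enumerate(cols)]
        groups = pd.Series([ds.groups[c] for c in cols], index=new_names)
        mat.columns = new_names
        return StudyDataset(ds.study_id, mat, groups, ds.platform_tag)
    if mode == "permute":
        labels = rng.permutation(ds.groups.to_numpy())
        groups = pd.Series(labels, index=ds.matrix.columns)
        return StudyDataset(ds.study_id, ds.matrix, groups, ds.platform_tag)
    raise ValueError(f"unknown resample mode {mode!r}; expected one of {RESAMPLE_MODES}")


def combined_pvalues(
    datasets: list[StudyDataset],
    genes: list[str],
    n_perm: int = 1000,
    s0: float | str = "auto",
    seeds: list[int] | None = None,
) -> pd.Series:
    """Fisher-combined SAM permutation p-values on a shared gene universe."""
    if seeds is None:
        seeds = list(range(len(datasets)))
    P = np.empty((len(genes), len(datasets)))
    for j, ds in enumerate(datasets):
        res, _ = sam_test(ds, n_perm=n_perm, s0=s0, seed=int(seeds[j]))
        P[:, j] = res.loc[genes, "p"].to_numpy()
    _, fisher_p = fisher_combine_matrix(P)
    fisher_p = np.maximum(fisher_p, np.nextafter(0, 1))
    return pd.Series(fisher_p, index=genes)


def score_network(
    graph: nx.Graph, p_by_gene: pd.Series, fdr: float = 0.001
) -> tuple[ScoredNetwork, "BumFit"]:
    """Fit the BUM to the combined p-values and score every network node.

    Nodes without a measured p-value get the score at p = 1 (the most
    conservative, maximally negative assignment for the fitted mixture).
    """
    fit = fit_bum(p_by_gene.to_numpy())
    scored = nx.Graph(graph)
    scores = score_pvalues(p_by_gene.to_numpy(), fit, fdr)
    lookup = dict(zip(p_by_gene.index, scores))
    default = float(score_pvalues(np.array([1.0]), fit, fdr)[0])
    for v in scored.nodes:
        scored.nodes[v]["score"] = float(lookup.get(v, default))
    return ScoredNetwork(graph=scored, fdr_level=fdr), fit


def detect_module(
    datasets: list[StudyDataset],
    graph: nx.Graph,
    fdr: float = 0.001,
    n_perm: int = 1000,
    s0: float | str = "auto",
    seed: int = 0,
    method: str = "auto",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> Module:
    """Single-pass module detection on the largest network component."""
    work = largest_component(graph)
    genes = common_genes(datasets)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31 - 1, size=len(datasets))
    p = combined_pvalues(datasets, genes, n_perm=n_perm, s0=s0, seeds=list(seeds))
    scored, _ = score_network(work, p, fdr)
    return max_scoring_subnetwork(scored, method=method, exact_limit=exact_limit)


def consensus_module(
    datasets: list[StudyDataset],
    graph: nx.Graph,
    n_iter: int = 100,
    fdr: float = 0.001,
    resample: str = "bootstrap",
    phi: float = 0.5,
    seed: int = 0,
    n_perm: int = 1000,
    s0: float | str = "auto",
    method: str = "auto",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> Module:
    """Consensus module over ``n_iter`` resampled detection passes.

    Consensus node score = occurrence frequency - ``phi``; the final module
    is the maximum-scoring subnetwork under these scores (empty when no
    node recurs more often than ``phi``). Deterministic under ``seed``.
    Iterations whose detection fails are logged and skipped; more than 50%
    failures aborts.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must be in (0, 1)")
    work = largest_component(graph)
    genes = common_genes(datasets)
    rng = np.random.default_rng(seed)

    node_count: dict = {v: 0 for v in work.nodes}
    edge_count: dict = {}
    n_fail = 0
    for it in range(n_iter):
        sam_seeds = rng.integers(2**31 - 1, size=len(datasets))
        try:
            ds_it = [resample_dataset(ds, resample, rng) for ds in datasets]
            p = combined_pvalues(ds_it, genes, n_perm=n_perm, s0=s0, seeds=list(sam_seeds))
            scored, _ = score_network(work, p, fdr)
            module = max_scoring_subnetwork(scored, method=method, exact_limit=exact_limit)
        except Exception:
            n_fail += 1
            logger.exception("consensus iteration %d failed; skipping", it)
            continue
        for v in module.nodes:
            node_count[v] += 1
        for e in module.edges:
            edge_count[e] = edge_count.get(e, 0) + 1

    n_ok = n_iter - n_fail
    if n_ok < n_iter / 2.0:
        raise RuntimeError(f"{n_fail}/{n_iter} consensus iterations failed")

    node_freq = {v: c / n_ok for v, c in node_count.items()}
    edge_freq = {e: c / n_ok for e, c in edge_count.items()}

    cons = nx.Graph(work)
    for v in cons.nodes:
        cons.nodes[v]["score"] = node_freq[v] - phi
    final = max_scoring_subnetwork(
        ScoredNetwork(graph=cons, fdr_level=fdr),
        method=method, exact_limit=exact_limit, allow_empty=True,
    )
    final.node_freq = {v: node_freq[v] for v in sorted(node_freq)}
    final.edge_freq = {canonical_edge(*e): f for e, f in sorted(edge_freq.items())}
    return final
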