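"""Generator contracts: determinism, planted signal, network structure."""

import networkx as nx
import numpy as np
import pytest

from metamodule.meta import smd_per_study
from metamodule.simulate import (
    SimulationConfig,
    network_graph,
    simulate_network,
    simulate_studies,
)


def _cfg(**kw):
    base = dict(
        k_studies=2, n_high=10, n_low=10, n_genes=200, deg_fraction=0.05,
        smd_range=(0.5, 0.8), heterogeneity_tau2=0.01, network_nodes=80,
        network_attach=2, planted_module_size=6, seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_is_bit_identical():
    a, _ = simulate_studies(_cfg())
    b, _ = simulate_studies(_cfg())
    for da, db in zip(a, b):
        assert (da.matrix.to_numpy() == db.matrix.to_numpy()).all()
        assert (da.groups == db.groups).all()
    ea = simulate_network(_cfg(), simulate_studies(_cfg())[1])
    eb = simulate_network(_cfg(), simulate_studies(_cfg())[1])
    assert ea == eb


def test_no_signal_case_has_no_degs_and_small_group_differences():
    datasets, truth = simulate_studies(_cfg(deg_fraction=0.0, n_high=50, n_low=50))
    assert truth.deg_genes == set()
    assert truth.planted_module_nodes == set()
    ds = datasets[0]
    diff = ds.matrix[ds.high_samples].mean(axis=1) - ds.matrix[ds.low_samples].mean(axis=1)
    # group means differ only by sampling noise: SE of the diff is sigma*sqrt(2/50)
    assert np.abs(diff).max() < 1.0 * np.sqrt(2 / 50) * 5


def test_large_sample_smd_matches_generating_value():
    cfg = _cfg(k_studies=1, n_high=1000, n_low=1000, n_genes=50,
               deg_fraction=0.5, smd_range=(0.7, 0.7), heterogeneity_tau2=0.0,
               network_nodes=50, planted_module_size=5)
    datasets, truth = simulate_studies(cfg)
    ds = datasets[0]
    hi, lo = ds.high_samples, ds.low_samples
    g, _ = smd_per_study(
        len(hi), len(lo),
        ds.matrix[hi].mean(axis=1).to_numpy(), ds.matrix[lo].mean(axis=1).to_numpy(),
        ds.matrix[hi].std(axis=1, ddof=1).to_numpy(), ds.matrix[lo].std(axis=1, ddof=1).to_numpy(),
    )
    for gene, true_smd in truth.per_gene_true_smd.items():
        i = list(ds.matrix.index).index(gene)
        assert g[i] == pytest.approx(true_smd, abs=0.1)


def test_rejects_groups_below_two_samples():
    with pytest.raises(ValueError):
        _cfg(n_high=1)


def test_network_is_simple_with_connected_planted_module():
    cfg = _cfg(network_nodes=500, network_attach=2, n_genes=600)
    datasets, truth = simulate_studies(cfg)
    edges = simulate_network(cfg, truth)
    g = network_graph(edges)
    assert nx.number_of_selfloops(g) == 0
    assert g.number_of_edges() == len(edges)  # no multi-edges collapsed away
    # closed-form BA edge count: (n - m) * m
    assert len(edges) == (500 - 2) * 2
    assert truth.planted_module_nodes <= truth.deg_genes
    assert nx.is_connected(g.subgraph(truth.planted_module_nodes))
    assert truth.planted_module_edges <= {tuple(sorted(e)) for e in g.edges}


def test_single_node_module_is_trivially_connected():
    cfg = _cfg(planted_module_size=1)
    _, truth = simulate_studies(cfg)
    simulate_network(cfg, truth)
    assert len(truth.planted_module_nodes) == 1
    assert truth.planted_module_edges == set()


def test_two_platform_dropout_shrinks_gene_universes_disjointly():
    cfg = _cfg(two_platform_dropout=True, n_genes=300, network_nodes=80)
    datasets, _ = simulate_studies(cfg)
    ga, gb = set(datasets[0].matrix.index), set(datasets[1].matrix.index)
    assert len(ga) == len(gb) == 300 - 30
    assert ga != gb
    assert len(ga & gb) == 300 - 60


def test_empirical_smd_converges_over_many_studies():
    cfg = _cfg(k_studies=20, n_high=40, n_low=40, n_genes=100, deg_fraction=0.1,
               smd_range=(0.6, 0.6), heterogeneity_tau2=0.0,
               network_nodes=60, planted_module_size=5, seed=17)
    datasets, truth = simulate_studies(cfg)
    gene = sorted(truth.deg_genes)[0]
    ests = []
    for ds in datasets:
        hi, lo = ds.high_samples, ds.low_samples
        row = ds.matrix.loc[gene]
        g, _ = smd_per_study(len(hi), len(lo), row[hi].mean(), row[lo].mean(),
                             row[hi].std(ddof=1), row[lo].std(ddof=1))
        ests.append(g)
    assert np.mean(ests) == pytest.approx(truth.per_gene_true_smd[gene], abs=0.12)
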