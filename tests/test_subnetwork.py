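"""Maximum-scoring subnetwork: exact optimality, heuristic bounds, connectivity."""

import networkx as nx
import numpy as np
import pytest

from metamodule.subnetwork import largest_component, max_scoring_subnetwork


def brute_force_best(graph):
    """Enumerate every connected induced subset via bitmask BFS (oracle)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    scores = [float(graph.nodes[v]["score"]) for v in nodes]
    best = -np.inf
    for mask in range(1, 1 << n):
        seen = frontier = mask & -mask
        while frontier:
            nxt, m = 0, frontier
            while m:
                b = m & -m
                nxt |= adj[b.bit_length() - 1] & mask & ~seen
                m ^= b
            seen |= nxt
            frontier = nxt
        if seen != mask:
            continue
        best = max(best, sum(scores[i] for i in range(n) if mask >> i & 1))
    return best


def _scored_path(scores):
    g = nx.path_graph(len(scores))
    for v, s in zip(g.nodes, scores):
        g.nodes[v]["score"] = float(s)
    return g


def test_bridging_a_cheap_negative_node_pays():
    m = max_scoring_subnetwork(_scored_path([2, -1, 2]), method="exact")
    assert m.nodes == {0, 1, 2}
    assert m.total_score == pytest.approx(3.0)


def test_expensive_bridge_is_refused():
    m = max_scoring_subnetwork(_scored_path([2, -5, 2]), method="exact")
    assert len(m.nodes) == 1
    assert m.total_score == pytest.approx(2.0)


def test_all_positive_returns_whole_graph(rng):
    g = nx.random_regular_graph(3, 10, seed=1)
    for v in g.nodes:
        g.nodes[v]["score"] = float(rng.uniform(0.1, 1))
    m = max_scoring_subnetwork(g, method="exact")
    assert m.nodes == set(g.nodes)


def test_all_negative_returns_best_single_node_or_empty():
    g = _scored_path([-3, -1, -2])
    m = max_scoring_subnetwork(g, method="exact")
    assert m.nodes == {1}
    e = max_scoring_subnetwork(g, method="exact", allow_empty=True)
    assert e.nodes == set()
    assert e.total_score == 0.0


@pytest.mark.parametrize("method", ["exact", "heuristic"])
def test_returned_module_is_connected(method, rng):
    for seed in range(5):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        for v in g.nodes:
            g.nodes[v]["score"] = float(rng.uniform(-2, 2))
        m = max_scoring_subnetwork(g, method=method)
        assert m.nodes
        assert nx.is_connected(g.subgraph(m.nodes))


def test_exact_matches_enumeration_oracle(rng):
    for trial in range(15):
        n = int(rng.integers(8, 14))
        g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        for v in g.nodes:
            g.nodes[v]["score"] = float(rng.uniform(-2, 2))
        m = max_scoring_subnetwork(g, method="exact")
        assert m.total_score == pytest.approx(brute_force_best(g))


def test_heuristic_bounded_by_exact_and_single_node(rng):
    for trial in range(10):
        g = nx.gnp_random_graph(12, 0.3, seed=trial)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        for v in g.nodes:
            g.nodes[v]["score"] = float(rng.uniform(-2, 2))
        exact = max_scoring_subnetwork(g, method="exact")
        heur = max_scoring_subnetwork(g, method="heuristic")
        best_single = max(g.nodes[v]["score"] for v in g.nodes)
        assert heur.total_score <= exact.total_score + 1e-9
        assert heur.total_score >= best_single - 1e-9


def test_disconnected_input_errors():
    g = nx.Graph()
    g.add_node("a", score=1.0)
    g.add_node("b", score=1.0)
    with pytest.raises(ValueError, match="connected"):
        max_scoring_subnetwork(g, method="exact")


def test_exact_above_size_limit_advises_heuristic():
    g = nx.path_graph(40)
    # alternating signs prevent the reductions from shrinking the graph
    for v in g.nodes:
        g.nodes[v]["score"] = -1.0 if v % 2 == 0 else 1.0
    with pytest.raises(ValueError, match="heuristic"):
        max_scoring_subnetwork(g, method="exact", exact_limit=10)


def test_largest_component_strips_self_loops():
    g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y"), ("a", "a")])
    lc = largest_component(g)
    assert set(lc.nodes) == {"a", "b", "c"}
    assert nx.number_of_selfloops(lc) == 0
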