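"""Maximum-scoring connected subnetwork ("active module") search.

Given a connected, simple, node-scored graph, find the connected node
subset maximizing the summed score. Exact solutions come from a
branch-and-bound enumeration of connected subsets after two safe
reductions (contracting edges between positive nodes; peeling negative
leaves); graphs still larger than the exact-size limit fall back to a
heuristic that links positively scored components through cheapest
(node-weighted Dijkstra) connector paths and then prunes.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from math import inf

import networkx as nx

from .datatypes import Module, ScoredNetwork, canonical_edge

logger = logging.getLogger(__name__)

EXACT_LIMIT_DEFAULT = 30


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Largest connected component with self-loops removed."""
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        return g
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp).copy()


def _as_scored_graph(net) -> nx.Graph:
    g = net.graph if isinstance(net, ScoredNetwork) else net
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    for v, data in g.nodes(data=True):
        if "score" not in data:
            raise ValueError(f"node {v!r} carries no score")
    return g


def _module_from_nodes(graph: nx.Graph, nodes) -> Module:
    nodes = set(nodes)
    sub = graph.subgraph(nodes)
    edges = {canonical_edge(u, v) for u, v in sub.edges}
    total = float(sum(graph.nodes[v]["score"] for v in nodes))
    return Module(nodes=nodes, edges=edges, total_score=total)


# ---------------------------------------------------------------------------
# reductions


def _reduce_graph(graph: nx.Graph) -> tuple[nx.Graph, dict]:
    """Contract positive-positive edges and peel negative leaves.

    Both preserve at least one optimal solution: a strictly positive
    neighbor of any optimal set can always be absorbed, and a negative leaf
    can never pay for itself. Returns the reduced graph (supernode scores
    summed) and a map supernode -> set of original nodes.
    """
    pos_nodes = [v for v, d in graph.nodes(data=True) if d["score"] > 0]
    comp_of = {}
    expands = {}
    g2 = nx.Graph()
    for i, comp in enumerate(nx.connected_components(graph.subgraph(pos_nodes))):
        name = ("supernode", i)
        expands[name] = set(comp)
        for v in comp:
            comp_of[v] = name
        g2.add_node(name, score=float(sum(graph.nodes[v]["score"] for v in comp)))
    for v, d in graph.nodes(data=True):
        if v not in comp_of:
            comp_of[v] = v
            expands[v] = {v}
            g2.add_node(v, score=float(d["score"]))
    for u, v in graph.edges:
        cu, cv = comp_of[u], comp_of[v]
        if cu != cv:
            g2.add_edge(cu, cv)

    # iteratively peel negative-score leaves
    changed = True
    while changed and g2.number_of_nodes() > 1:
        changed = False
        for v in list(g2.nodes):
            if g2.degree(v) <= 1 and g2.nodes[v]["score"] <= 0 and g2.number_of_nodes() > 1:
                g2.remove_node(v)
                changed = True
    return g2, expands


# ---------------------------------------------------------------------------
# exact branch-and-bound


def _exact_search(adj: list[int], scores: list[float]) -> tuple[float, int]:
    """Best-scoring connected subset via rooted enumeration with a bound.

    Subsets are enumerated once each, rooted at their lowest-index member;
    the bound adds all still-available positive scores to the current
    subset score.
    """
    n = len(scores)
    best_score = -inf
    best_set = 0
    pos = [max(s, 0.0) for s in scores]

    def recurse(S: int, score: float, ext: int, banned: int, avail_pos: float) -> None:
        nonlocal best_score, best_set
        if score > best_score:
            best_score, best_set = score, S
        if score + avail_pos <= best_score or not ext:
            return
        v = (ext & -ext).bit_length() - 1  # lowest candidate
        bit = 1 << v
        # include v
        new_ext = (ext | adj[v]) & ~(S | bit) & ~banned
        recurse(S | bit, score + scores[v], new_ext, banned, avail_pos - pos[v])
        # exclude v permanently
        recurse(S, score, ext & ~bit, banned | bit, avail_pos - pos[v])

    total_pos = sum(pos)
    banned_roots = 0
    for r in range(n):
        bit = 1 << r
        avail = total_pos - sum(pos[i] for i in range(r))
        recurse(bit, scores[r], adj[r] & ~banned_roots & ~bit, banned_roots, avail - pos[r])
        banned_roots |= bit
    return best_score, best_set


def _solve_exact(graph: nx.Graph) -> set:
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    scores = [float(graph.nodes[v]["score"]) for v in nodes]
    _, best_set = _exact_search(adj, scores)
    return {nodes[i] for i in range(len(nodes)) if best_set >> i & 1}


# ---------------------------------------------------------------------------
# heuristic


def _node_cost(graph: nx.Graph, v) -> float:
    return max(0.0, -float(graph.nodes[v]["score"]))


def _dijkstra_from_set(graph: nx.Graph, sources: set) -> tuple[dict, dict]:
    """Cheapest node-weighted connector cost from a source set to every node."""
    dist: dict = {}
    parent: dict = {}
    heap = []
    counter = itertools.count()
    for s in sources:
        for w in graph.neighbors(s):
            if w in sources:
                continue
            c = _node_cost(graph, w)
            if c < dist.get(w, inf):
                dist[w] = c
                parent[w] = s
                heapq.heappush(heap, (c, next(counter), w))
    while heap:
        d, _, v = heapq.heappop(heap)
        if d > dist.get(v, inf):
            continue
        for w in graph.neighbors(v):
            if w in sources:
                continue
            nd = d + _node_cost(graph, w)
            if nd < dist.get(w, inf):
                dist[w] = nd
                parent[w] = v
                heapq.heappush(heap, (nd, next(counter), w))
    return dist, parent


def _connector_path(parent: dict, sources: set, v) -> list:
    path = []
    while v not in sources:
        path.append(v)
        v = parent[v]
    return path


def _prune(graph: nx.Graph, nodes: set) -> set:
    """Drop negative non-articulation nodes while that raises the score."""
    nodes = set(nodes)
    while len(nodes) > 1:
        sub = graph.subgraph(nodes)
        arts = set(nx.articulation_points(sub))
        droppable = [
            v for v in nodes
            if graph.nodes[v]["score"] < 0 and v not in arts
        ]
        if not droppable:
            break
        nodes.discard(min(droppable, key=lambda v: graph.nodes[v]["score"]))
    return nodes


def _solve_heuristic(graph: nx.Graph) -> set:
    scores = {v: float(graph.nodes[v]["score"]) for v in graph.nodes}
    best_single = max(graph.nodes, key=lambda v: scores[v])
    pos = [v for v in graph.nodes if scores[v] > 0]
    if not pos:
        return {best_single}

    comps = [set(c) for c in nx.connected_components(graph.subgraph(pos))]
    comp_score = [sum(scores[v] for v in c) for c in comps]
    order = sorted(range(len(comps)), key=lambda i: -comp_score[i])
    solution = set(comps[order[0]])
    remaining = [i for i in order[1:]]

    while remaining:
        dist, parent = _dijkstra_from_set(graph, solution)
        best_gain, best_i, best_entry = 0.0, None, None
        for i in remaining:
            entry = min((v for v in comps[i] if v in dist), key=lambda v: dist[v], default=None)
            if entry is None:
                continue
            gain = comp_score[i] - dist[entry]
            if gain > best_gain:
                best_gain, best_i, best_entry = gain, i, entry
        if best_i is None:
            break
        solution |= set(_connector_path(parent, solution, best_entry))
        solution |= comps[best_i]
        remaining.remove(best_i)

    solution = _prune(graph, solution)
    if sum(scores[v] for v in solution) < scores[best_single]:
        return {best_single}
    return solution


# ---------------------------------------------------------------------------
# public entry point


def max_scoring_subnetwork(
    net,
    method: str = "auto",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
    allow_empty: bool = False,
) -> Module:
    """Maximum-scoring connected subnetwork of a node-scored graph.

    ``method`` is ``"exact"`` (guaranteed optimal; errors if the reduced
    graph exceeds ``exact_limit`` nodes), ``"heuristic"``, or ``"auto"``
    (exact when the reduced graph is small enough, heuristic otherwise).
    With all scores negative the best single node is returned, or the empty
    module (score 0) when ``allow_empty`` is set.
    """
    graph = _as_scored_graph(net)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError(
            "graph must be connected; run largest_component() before solving"
        )
    if method not in {"exact", "heuristic", "auto"}:
        raise ValueError(f"unknown method {method!r}")

    reduced, expands = _reduce_graph(graph)
    use_exact = method == "exact" or (
        method == "auto" and reduced.number_of_nodes() <= exact_limit
    )
    if method == "exact" and reduced.number_of_nodes() > exact_limit:
        raise ValueError(
            f"reduced graph has {reduced.number_of_nodes()} nodes "
            f"(> exact limit {exact_limit}); use method='heuristic'"
        )

    if use_exact:
        chosen = _solve_exact(reduced)
        nodes = set().union(*(expands[v] for v in chosen)) if chosen else set()
    else:
        nodes = _solve_heuristic(graph)

    if not nodes or sum(graph.nodes[v]["score"] for v in nodes) < 0:
        if allow_empty:
            return Module(nodes=set(), edges=set(), total_score=0.0)
        best = max(graph.nodes, key=lambda v: graph.nodes[v]["score"])
        return _module_from_nodes(graph, {best})
    return _module_from_nodes(graph, nodes)
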