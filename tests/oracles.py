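"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms under test: betweenness comes
from exhaustive simple-path enumeration in exact rational arithmetic,
eigenvector centrality from a dense symmetric eigendecomposition, and
modularity optimality from enumerating every partition.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np

from tagnet.graph import HashtagGraph, edge_key


def enumerate_simple_paths(adj, s, t):
    """All simple paths s -> t as node tuples (DFS)."""
    paths = []
    stack = [(s, [s], {s})]
    while stack:
        u, path, seen = stack.pop()
        if u == t:
            paths.append(tuple(path))
            continue
        for v in adj[u]:
            if v not in seen:
                stack.append((v, path + [v], seen | {v}))
    return paths


def brute_force_betweenness(graph: HashtagGraph, mode: str):
    """Node and edge betweenness by enumerating every shortest path.

    Returns (node_scores, edge_scores) as exact Fractions; pair
    dependencies are split equally among tied shortest paths, each
    unordered pair counted once, path endpoints excluded for nodes and
    included for edges.
    """
    if mode == "inverse_weight":
        lengths = {e: Fraction(1, int(w)) for e, w in graph.edges.items()}
    else:
        lengths = {e: Fraction(1) for e in graph.edges}
    adj = {v: [] for v in graph.nodes}
    for (u, v) in graph.edges:
        adj[u].append(v)
        adj[v].append(u)

    node_bc = dict.fromkeys(graph.nodes, Fraction(0))
    edge_bc = dict.fromkeys(graph.edges, Fraction(0))
    for s, t in combinations(sorted(graph.nodes), 2):
        paths = enumerate_simple_paths(adj, s, t)
        if not paths:
            continue
        plen = {
            p: sum(lengths[edge_key(p[i], p[i + 1])] for i in range(len(p) - 1))
            for p in paths
        }
        dmin = min(plen.values())
        shortest = [p for p in paths if plen[p] == dmin]
        share = Fraction(1, len(shortest))
        for p in shortest:
            for v in p[1:-1]:
                node_bc[v] += share
            for i in range(len(p) - 1):
                edge_bc[edge_key(p[i], p[i + 1])] += share
    return node_bc, edge_bc


def dense_eigenvector(graph: HashtagGraph):
    """Leading eigenvector of the weighted adjacency, max-scaled, via
    numpy's dense symmetric eigendecomposition."""
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for (u, v), w in graph.edges.items():
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    vals, vecs = np.linalg.eigh(A)
    lead = np.abs(vecs[:, int(np.argmax(vals))])
    lead = lead / lead.max()
    return dict(zip(nodes, lead))


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


def exhaustive_max_modularity(graph: HashtagGraph, modularity_fn):
    """Global modularity maximum over all partitions (small graphs only)."""
    best_q, best_p = -np.inf, None
    for p in all_partitions(sorted(graph.nodes)):
        membership = {v: i for i, block in enumerate(p) for v in block}
        q = modularity_fn(graph, membership)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p
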