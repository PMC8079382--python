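"""Centrality measures computed from scratch.

Eigenvector centrality is the leading eigenvector of the weighted
adjacency matrix, found by power iteration and scaled so the maximum
score is exactly 1.  Node and edge betweenness use Brandes'
single-source accumulation of pair dependencies; the weighted mode
treats edge length as 1/weight, so frequently co-posted hashtags are
"close".  An ``exact`` switch runs the betweenness machinery in
rational arithmetic (:class:`fractions.Fraction`) for oracle-grade
comparisons.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import ConfigError, ConvergenceError, DataError
from .graph import HashtagGraph, Pair

MODES = ("unweighted", "inverse_weight")


@dataclass
class CentralityScores:
    measure: str
    node_scores: dict[str, float] | None = None
    edge_scores: dict[Pair, float] | None = None
    node_scores_normalized: dict[str, float] | None = None
    edge_scores_normalized: dict[Pair, float] | None = None
    normalized: bool = False
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Eigenvector centrality


def eigenvector_centrality(
    graph: HashtagGraph,
    tolerance: float = 1e-10,
    max_iter: int = 1000,
    start: dict[str, float] | None = None,
) -> CentralityScores:
    """Power iteration on the weighted adjacency of the giant component.

    Scores are scaled so the maximum is exactly 1.  On disconnected
    graphs only the largest component (by node count, ties by summed
    weight) is scored; all other nodes get 0 and a warning is emitted.
    """
    if graph.n_nodes == 0:
        raise DataError("eigenvector centrality of an empty graph")
    comps = graph.connected_components()
    giant = comps[0]
    if len(comps) > 1:
        warnings.warn(
            f"graph has {len(comps)} components; eigenvector centrality computed "
            f"on the largest ({len(giant)} nodes), others scored 0",
            stacklevel=2,
        )
    scores = dict.fromkeys(graph.nodes, 0.0)
    if len(giant) == 1:
        scores[giant[0]] = 1.0
        return CentralityScores(
            "eigenvector", node_scores=scores, node_scores_normalized=scores,
            normalized=True, params={"tolerance": tolerance, "max_iter": max_iter},
        )

    idx = {v: i for i, v in enumerate(giant)}
    n = len(giant)
    A = np.zeros((n, n))
    giant_set = set(giant)
    for (u, v), w in graph.edges.items():
        if u in giant_set and v in giant_set:
            A[idx[u], idx[v]] = w
            A[idx[v], idx[u]] = w

    # Power-iterate the shifted matrix A + sI with s = max row sum.  The
    # shift keeps the Perron vector but pushes the smallest eigenvalue to
    # >= 0, so bipartite components (|lambda_min| = lambda_max) cannot
    # make the iteration oscillate.
    shift = float(A.sum(axis=1).max())
    B = A + shift * np.eye(n)
    if start is None:
        x = np.ones(n) / np.sqrt(n)  # strictly positive start
    else:
        x = np.array([float(start[v]) for v in giant])
        if np.any(x <= 0):
            raise ConfigError("start vector must be strictly positive")
        x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(max_iter):
        y = B @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            # giant component with no internal weight cannot happen for
            # n >= 2 picked from connected_components, but guard anyway
            raise ConvergenceError("adjacency annihilated the iterate", residual=np.inf)
        x_new = y / norm
        lam = float(x_new @ (A @ x_new))
        residual = float(np.max(np.abs(A @ x_new - lam * x_new)))
        x = x_new
        if residual <= tolerance:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual=residual,
        )

    x = np.abs(x)  # Perron vector is non-negative; kill sign noise
    x /= x.max()
    for v, i in idx.items():
        scores[v] = float(x[i])
    return CentralityScores(
        "eigenvector",
        node_scores=scores,
        node_scores_normalized=scores,
        normalized=True,
        params={
            "tolerance": tolerance,
            "max_iter": max_iter,
            "eigenvalue": lam,
            "component_size": n,
        },
    )


# ---------------------------------------------------------------------------
# Brandes betweenness


def _edge_lengths(graph: HashtagGraph, mode: str, exact: bool):
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    one = Fraction(1) if exact else 1.0
    lengths: dict[Pair, object] = {}
    for e, w in graph.edges.items():
        if mode == "inverse_weight":
            if w <= 0:
                raise DataError(f"non-positive weight on edge {e} in inverse_weight mode")
            if exact:
                wf = Fraction(w).limit_denominator(10**12) if isinstance(w, float) else Fraction(w)
                lengths[e] = 1 / wf
            else:
                lengths[e] = 1.0 / w
        else:
            lengths[e] = one
    return lengths


def _sssp(source, adj, lengths, unweighted: bool, exact: bool):
    """Shortest-path DAG from one source: order of settlement, sigma
    (path counts), predecessor lists.  BFS when unweighted, Dijkstra
    otherwise."""
    zero = Fraction(0) if exact else 0.0
    dist = {source: zero}
    sigma = {source: 1}
    pred: dict = {source: []}
    order = []
    if unweighted:
        q = deque([source])
        while q:
            u = q.popleft()
            order.append(u)
            for v in adj[u]:
                d = dist[u] + 1
                if v not in dist:
                    dist[v] = d
                    sigma[v] = 0
                    pred[v] = []
                    q.append(v)
                if dist[v] == d:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
    else:
        seen = set()
        counter = 0
        heap = [(zero, counter, source)]
        while heap:
            d, _, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            order.append(u)
            for v, length in adj[u].items():
                nd = d + length
                if v not in dist or nd < dist[v]:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    pred[v] = [u]
                    counter += 1
                    heapq.heappush(heap, (nd, counter, v))
                elif nd == dist[v] and u not in pred[v]:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
    return order, sigma, pred


def _component_sizes(graph: HashtagGraph) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for comp in graph.connected_components():
        for v in comp:
            sizes[v] = len(comp)
    return sizes


def betweenness_centrality(
    graph: HashtagGraph,
    mode: str = "inverse_weight",
    normalized: bool = True,
    exact: bool = False,
) -> CentralityScores:
    """Brandes node betweenness; each unordered pair counted once.

    Disconnected graphs are handled per component, and normalization
    divides by the component-level constant ``(n-1)(n-2)/2``.
    """
    lengths = _edge_lengths(graph, mode, exact)
    adj: dict[str, dict] = {v: {} for v in graph.nodes}
    for (u, v), length in lengths.items():
        adj[u][v] = length
        adj[v][u] = length

    zero = Fraction(0) if exact else 0.0
    bc = dict.fromkeys(graph.nodes, zero)
    unweighted = mode == "unweighted"
    for s in graph.nodes:
        order, sigma, pred = _sssp(s, adj, lengths, unweighted, exact)
        delta = dict.fromkeys(order, zero)
        for w in reversed(order):
            for v in pred[w]:
                if exact:
                    delta[v] += Fraction(sigma[v], sigma[w]) * (1 + delta[w])
                else:
                    delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    half = Fraction(1, 2) if exact else 0.5
    bc = {v: x * half for v, x in bc.items()}  # undirected: each pair seen twice

    sizes = _component_sizes(graph)
    norm_scores = {}
    for v, x in bc.items():
        n = sizes[v]
        denom = (n - 1) * (n - 2) / 2 if not exact else Fraction((n - 1) * (n - 2), 2)
        norm_scores[v] = x / denom if n > 2 else zero
    return CentralityScores(
        "betweenness",
        node_scores=bc,
        node_scores_normalized=norm_scores,
        normalized=normalized,
        params={"mode": mode, "exact": exact},
    )


def edge_betweenness(
    graph: HashtagGraph,
    mode: str = "inverse_weight",
    normalized: bool = True,
    exact: bool = False,
) -> CentralityScores:
    """Brandes edge betweenness: per-edge shortest-path load, endpoints
    included, each unordered pair counted once, ties split equally."""
    lengths = _edge_lengths(graph, mode, exact)
    adj: dict[str, dict] = {v: {} for v in graph.nodes}
    for (u, v), length in lengths.items():
        adj[u][v] = length
        adj[v][u] = length

    zero = Fraction(0) if exact else 0.0
    ebc = dict.fromkeys(graph.edges, zero)
    unweighted = mode == "unweighted"
    for s in graph.nodes:
        order, sigma, pred = _sssp(s, adj, lengths, unweighted, exact)
        delta = dict.fromkeys(order, zero)
        for w in reversed(order):
            for v in pred[w]:
                if exact:
                    c = Fraction(sigma[v], sigma[w]) * (1 + delta[w])
                else:
                    c = sigma[v] / sigma[w] * (1 + delta[w])
                key = (v, w) if v < w else (w, v)
                ebc[key] += c
                delta[v] += c
    half = Fraction(1, 2) if exact else 0.5
    ebc = {e: x * half for e, x in ebc.items()}

    sizes = _component_sizes(graph)
    norm_scores = {}
    for (u, v), x in ebc.items():
        n = sizes[u]
        denom = n * (n - 1) / 2 if not exact else Fraction(n * (n - 1), 2)
        norm_scores[(u, v)] = x / denom if n > 1 else zero
    return CentralityScores(
        "edge_betweenness",
        edge_scores=ebc,
        edge_scores_normalized=norm_scores,
        normalized=normalized,
        params={"mode": mode, "exact": exact},
    )


def degree_and_strength(graph: HashtagGraph) -> tuple[CentralityScores, CentralityScores]:
    """Degree (incident edge count) and strength (incident weight sum),
    each with max-normalized companions."""
    deg = {v: float(d) for v, d in graph.degree().items()}
    stren = graph.strength()
    max_d = max(deg.values(), default=0.0)
    max_s = max(stren.values(), default=0.0)
    deg_n = {v: (d / max_d if max_d else 0.0) for v, d in deg.items()}
    stren_n = {v: (s / max_s if max_s else 0.0) for v, s in stren.items()}
    return (
        CentralityScores("degree", node_scores=deg, node_scores_normalized=deg_n,
                         normalized=True),
        CentralityScores("strength", node_scores=stren, node_scores_normalized=stren_n,
                         normalized=True),
    )
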