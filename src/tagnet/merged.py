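"""Cross-area merged network and bridge-hashtag identification.

Per-area co-occurrence counts are summed tag-pair-wise; the most
frequent pairs (1400 by default) form the global graph.  Bridges are
ranked by betweenness and annotated with the number of distinct areas
reachable through their neighbours and an articulation-point flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .centrality import CentralityScores, betweenness_centrality, eigenvector_centrality
from .errors import ConfigError, DataError
from .graph import HashtagGraph, Pair


@dataclass
class MergedGraph:
    underlying: HashtagGraph
    area_tags: dict[str, set[str]] = field(default_factory=dict)
    pair_counts: dict[Pair, float] = field(default_factory=dict)
    linkage_coverage: float = 1.0


def merge_pair_counts(
    graphs: list[HashtagGraph],
) -> tuple[dict[Pair, float], dict[str, set[str]], dict[str, int]]:
    """Sum per-area edge weights; record which areas each tag came from.

    Returns (pair_counts, area_tags, summed node frequencies).
    """
    if not graphs:
        raise ConfigError("merge requires at least one graph")
    pair_counts: dict[Pair, float] = {}
    area_tags: dict[str, set[str]] = {}
    freqs: dict[str, int] = {}
    for g in graphs:
        for tag, f in g.nodes.items():
            area_tags.setdefault(tag, set()).add(g.area_name)
            freqs[tag] = freqs.get(tag, 0) + f
        for pair, w in g.edges.items():
            pair_counts[pair] = pair_counts.get(pair, 0) + w
    return pair_counts, area_tags, freqs


def select_top_pairs(
    pair_counts: dict[Pair, float],
    n: int = 1400,
    area_tags: dict[str, set[str]] | None = None,
    node_freqs: dict[str, int] | None = None,
) -> MergedGraph:
    """Keep the n heaviest pairs (ties lexicographic on the pair) and
    report the linkage coverage they account for."""
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    ranked = sorted(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = ranked[:n]
    total = sum(pair_counts.values())
    coverage = (sum(w for _, w in kept) / total) if total else 1.0

    graph = HashtagGraph(area_name="merged")
    for (u, v), w in kept:
        graph.edges[(u, v)] = w
        for tag in (u, v):
            if tag not in graph.nodes:
                graph.nodes[tag] = (node_freqs or {}).get(tag, 0)
    tags = {t: set(area_tags.get(t, set())) for t in graph.nodes} if area_tags else {
        t: set() for t in graph.nodes
    }
    return MergedGraph(
        underlying=graph,
        area_tags=tags,
        pair_counts=dict(pair_counts),
        linkage_coverage=coverage,
    )


def merge_graphs(graphs: list[HashtagGraph], n_pairs: int = 1400) -> MergedGraph:
    """Convenience wrapper: merge counts then select the top pairs."""
    pair_counts, area_tags, freqs = merge_pair_counts(graphs)
    return select_top_pairs(pair_counts, n=n_pairs, area_tags=area_tags, node_freqs=freqs)


def articulation_points(graph: HashtagGraph) -> set[str]:
    """Nodes whose removal increases the component count (iterative
    Hopcroft–Tarjan lowpoint DFS)."""
    adj = {u: sorted(nbrs) for u, nbrs in graph.adjacency().items()}
    disc: dict[str, int] = {}
    low: dict[str, int] = {}
    points: set[str] = set()
    timer = 0
    for root in sorted(graph.nodes):
        if root in disc:
            continue
        root_children = 0
        stack: list[tuple[str, str | None, int]] = [(root, None, 0)]
        while stack:
            u, parent, i = stack.pop()
            if i == 0:
                disc[u] = low[u] = timer
                timer += 1
            if i < len(adj[u]):
                stack.append((u, parent, i + 1))
                v = adj[u][i]
                if v not in disc:
                    if u == root:
                        root_children += 1
                    stack.append((v, u, 0))
                elif v != parent:
                    low[u] = min(low[u], disc[v])
            else:
                if parent is not None:
                    low[parent] = min(low[parent], low[u])
                    if parent != root and low[u] >= disc[parent]:
                        points.add(parent)
        if root_children > 1:
            points.add(root)
    return points


def bridge_hashtags(
    merged: MergedGraph, k: int | None = None, mode: str = "inverse_weight"
) -> list[dict]:
    """Rank nodes by betweenness on the merged graph.

    Each entry reports the betweenness score, the number of distinct
    areas among the node's neighbours' provenance tags, and whether the
    node is an articulation point.
    """
    graph = merged.underlying
    if graph.n_nodes == 0:
        raise DataError("bridge ranking on an empty merged graph")
    scores = betweenness_centrality(graph, mode=mode, normalized=True)
    aps = articulation_points(graph)
    adj = graph.adjacency()
    rows = []
    for tag in graph.nodes:
        neighbour_areas: set[str] = set()
        for nb in adj[tag]:
            neighbour_areas |= merged.area_tags.get(nb, set())
        rows.append(
            {
                "hashtag": tag,
                "betweenness": scores.node_scores[tag],
                "betweenness_normalized": scores.node_scores_normalized[tag],
                "n_neighbour_areas": len(neighbour_areas),
                "articulation_point": tag in aps,
            }
        )
    rows.sort(key=lambda r: (-r["betweenness"], r["hashtag"]))
    return rows[:k] if k is not None else rows


def merged_eigenvector(merged: MergedGraph, **kwargs) -> CentralityScores:
    """Eigenvector centrality of the merged graph (delegation)."""
    return eigenvector_centrality(merged.underlying, **kwargs)
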