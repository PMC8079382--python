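"""Per-area hashtag co-occurrence network construction.

The paper-style recipe: count per-tag post frequencies, keep the most
frequent tags (150 by default, the query tag excluded), connect two
tags with an edge weighted by the number of posts containing both, and
normalize strengths/weights by their maxima for presentation.
"""

from __future__ import annotations

import warnings
from itertools import combinations

from .corpus import Corpus
from .errors import ConfigError, DataError
from .graph import HashtagGraph


def hashtag_frequencies(corpus: Corpus) -> dict[str, int]:
    """Posts-containing-tag counts (a tag counts once per post)."""
    freqs: dict[str, int] = {}
    for post in corpus:
        for tag in post.hashtags:
            freqs[tag] = freqs.get(tag, 0) + 1
    return freqs


def select_top_hashtags(
    freqs: dict[str, int], n: int = 150, exclude: set[str] | None = None
) -> list[str]:
    """Top-n tags by frequency (desc), ties lexicographic (asc);
    excluded tags (the query tag, typically) are dropped before ranking."""
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    exclude = exclude or set()
    ranked = sorted(
        (t for t in freqs if t not in exclude),
        key=lambda t: (-freqs[t], t),
    )
    return ranked[:n]


def build_cooccurrence_graph(corpus: Corpus, selected: list[str]) -> HashtagGraph:
    """Weighted co-occurrence graph over the selected tags.

    Every unordered pair of selected tags present in a post increments
    that pair's weight by one; selected tags that never co-occur stay
    as isolated nodes.
    """
    if not selected:
        raise ConfigError("selected hashtag list must be non-empty")
    sel = set(selected)
    if len(sel) != len(selected):
        raise ConfigError("selected hashtag list contains duplicates")
    freqs = hashtag_frequencies(corpus)
    graph = HashtagGraph(area_name=corpus.area_name)
    for tag in selected:
        graph.nodes[tag] = freqs.get(tag, 0)
    for post in corpus:
        present = sorted(sel & post.hashtags)
        for u, v in combinations(present, 2):
            graph.edges[(u, v)] = graph.edges.get((u, v), 0) + 1
    graph.validate()
    return graph


def normalize_strength(graph: HashtagGraph) -> HashtagGraph:
    """Attach node strengths and max-normalized strengths/weights.

    Raw weights are kept; the normalized maps satisfy max == 1 whenever
    the graph has an edge.  An edgeless graph gets all-zero normalized
    values and a warning.
    """
    strengths = graph.strength()
    graph.node_strength = strengths
    if not graph.edges:
        warnings.warn(
            f"graph {graph.area_name!r} has no edges; normalized strengths set to 0",
            stacklevel=2,
        )
        graph.normalized_strength = dict.fromkeys(graph.nodes, 0.0)
        graph.normalized_weights = {}
        return graph
    max_s = max(strengths.values())
    max_w = max(graph.edges.values())
    graph.normalized_strength = {v: s / max_s for v, s in strengths.items()}
    graph.normalized_weights = {e: w / max_w for e, w in graph.edges.items()}
    return graph


def cooccurrence_coverage(corpus: Corpus, selected: list[str]) -> float:
    """Fraction of posts touching the selection that contain >= 2
    selected tags — the cohesion rationale behind the top-150 rule."""
    if not selected:
        raise ConfigError("selected hashtag list must be non-empty")
    sel = set(selected)
    touched = 0
    multi = 0
    for post in corpus:
        k = len(sel & post.hashtags)
        if k >= 1:
            touched += 1
        if k >= 2:
            multi += 1
    if touched == 0:
        raise DataError("no post contains any selected hashtag; coverage undefined")
    return multi / touched
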