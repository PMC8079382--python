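import numpy as np
import pytest

from tagnet.corpus import Corpus, Post
from tagnet.graph import HashtagGraph, edge_key


def make_graph(edges, weights=None, extra_nodes=(), area="test"):
    """Build a HashtagGraph from an edge list; node frequencies default
    to a safe upper bound (max incident weight) so invariants hold."""
    g = HashtagGraph(area_name=area)
    for i, (u, v) in enumerate(edges):
        w = weights[i] if weights is not None else 1
        g.edges[edge_key(u, v)] = w
    freq: dict[str, float] = {}
    for (u, v), w in g.edges.items():
        freq[u] = freq.get(u, 0) + w
        freq[v] = freq.get(v, 0) + w
    for n, f in freq.items():
        g.nodes[n] = int(f)
    for n in extra_nodes:
        g.nodes.setdefault(n, 0)
    g.validate()
    return g


def make_post(pid, tags, user="u1", ts="2019-06-01T12:00:00Z", label=None, topic=None):
    return Post(pid, user, ts, frozenset(tags), label, topic)


def make_corpus(tagsets, area="test", **kw):
    return Corpus(area, [make_post(f"p{i}", ts, **kw) for i, ts in enumerate(tagsets)])


def random_connected_graph(rng, n_max=10, p=0.4, weight_range=(1, 5)):
    """Erdos–Renyi graph conditioned on connectedness, integer weights."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        nodes = [f"n{i:02d}" for i in range(n)]
        edges, weights = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges.append((nodes[i], nodes[j]))
                    weights.append(int(rng.integers(weight_range[0], weight_range[1] + 1)))
        if not edges:
            continue
        g = make_graph(edges, weights)
        if len(g.nodes) == n and len(g.connected_components()) == 1:
            return g


@pytest.fixture
def two_clique_bridge():
    """Two unit-weight K3 cliques joined by one bridge edge."""
    return make_graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
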