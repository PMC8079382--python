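"""Greedy modularity communities and CES label suggestion.

Agglomeration follows Clauset–Newman–Moore: start from singletons,
repeatedly merge the adjacent pair of communities with the largest
modularity gain, record the dendrogram, and cut where modularity peaks.
Ties are broken by the lexicographically least member hashtag so the
output is platform-independent.  Modularity is the weighted Newman
quality ``Q = sum_c [W_c/W - (S_c/2W)^2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .graph import HashtagGraph


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    n_communities: int
    modularity: float
    dendrogram: list[tuple[str, str, float]]  # (rep_a, rep_b, Q after merge)
    cut_index: int  # number of merges applied at the returned cut

    def communities(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for tag, c in self.membership.items():
            out.setdefault(c, []).append(tag)
        return [sorted(out[c]) for c in sorted(out)]


def modularity(graph: HashtagGraph, membership: dict[str, int]) -> float:
    """Weighted Newman modularity of a node partition."""
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise DataError(f"membership missing nodes: {sorted(missing)[:5]}")
    W = graph.total_weight()
    if W == 0:
        return 0.0
    intra: dict[int, float] = {}
    stren: dict[int, float] = {}
    for (u, v), w in graph.edges.items():
        cu, cv = membership[u], membership[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
        stren[cu] = stren.get(cu, 0.0) + w
        stren[cv] = stren.get(cv, 0.0) + w
    q = 0.0
    for c in set(membership.values()):
        wc = intra.get(c, 0.0)
        sc = stren.get(c, 0.0)
        q += wc / W - (sc / (2 * W)) ** 2
    return q


def fast_greedy_communities(
    graph: HashtagGraph, force_k: int | None = None
) -> CommunityPartition:
    """CNM agglomeration on the weighted graph.

    Only adjacent communities are ever merged (a cross-component merge
    can never raise Q), so on a disconnected graph the dendrogram has
    ``n - n_components`` merges and components are labelled
    independently.  ``force_k`` cuts the dendrogram at exactly k
    communities instead of at maximum modularity.
    """
    if graph.n_nodes == 0:
        raise DataError("community detection on an empty graph")
    W = graph.total_weight()
    nodes = sorted(graph.nodes)
    if W == 0:
        membership = {v: i for i, v in enumerate(nodes)}
        return CommunityPartition(membership, len(nodes), 0.0, [], 0)

    # community state; community id = its lexicographically least member
    members: dict[str, list[str]] = {v: [v] for v in nodes}
    e: dict[str, dict[str, float]] = {v: {} for v in nodes}  # inter-community weight
    a: dict[str, float] = dict.fromkeys(nodes, 0.0)  # S_c / 2W
    for (u, v), w in graph.edges.items():
        e[u][v] = e[u].get(v, 0.0) + w
        e[v][u] = e[v].get(u, 0.0) + w
        a[u] += w / (2 * W)
        a[v] += w / (2 * W)

    q = -sum(x * x for x in a.values())  # singleton partition
    trace: list[float] = [q]
    merges: list[tuple[str, str, float]] = []

    while True:
        best = None
        best_gain = None
        for ci in sorted(e):
            for cj, wij in e[ci].items():
                if cj <= ci:
                    continue
                gain = 2 * (wij / (2 * W) - a[ci] * a[cj])
                if best_gain is None or gain > best_gain or (
                    gain == best_gain and (ci, cj) < best
                ):
                    best_gain = gain
                    best = (ci, cj)
        if best is None:
            break  # no adjacent pairs left (one community per component)
        ci, cj = best
        # merge cj into ci (ci < cj, so the id stays the least member)
        q += best_gain
        merges.append((ci, cj, q))
        trace.append(q)
        members[ci].extend(members.pop(cj))
        a[ci] += a.pop(cj)
        for ck, w in e.pop(cj).items():
            if ck == ci:
                continue
            e[ck].pop(cj, None)
            e[ci][ck] = e[ci].get(ck, 0.0) + w
            e[ck][ci] = e[ci][ck]
        e[ci].pop(cj, None)

    if force_k is not None:
        n_comp_final = len(members)  # communities left after all merges
        target = max(force_k, n_comp_final)
        cut = max(0, len(nodes) - target)
        cut = min(cut, len(merges))
    else:
        cut = int(max(range(len(trace)), key=lambda i: trace[i]))

    # replay merges up to the cut
    parent = {v: v for v in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ci, cj, _ in merges[:cut]:
        parent[find(cj)] = find(ci)

    groups: dict[str, list[str]] = {}
    for v in nodes:
        groups.setdefault(find(v), []).append(v)
    reps = sorted(groups, key=lambda r: min(groups[r]))
    membership = {}
    for idx, r in enumerate(reps):
        for v in groups[r]:
            membership[v] = idx
    return CommunityPartition(
        membership=membership,
        n_communities=len(reps),
        modularity=modularity(graph, membership),
        dendrogram=merges,
        cut_index=cut,
    )


# ---------------------------------------------------------------------------
# CES label suggestion


@dataclass
class CESLexicon:
    """Cultural-ecosystem-services cue sets: class name -> cue hashtags."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.classes = {k: {t.lower() for t in v} for k, v in self.classes.items()}


OTHER_LABEL = "Other"


def suggest_ces_labels(
    partition: CommunityPartition,
    lexicon: CESLexicon,
    graph: HashtagGraph,
) -> dict[int, list[tuple[str, float]]]:
    """Score each community against each CES class by cue-hit fraction.

    Returns, per community, classes ranked by (score desc, name asc)
    keeping only non-zero scores; communities with no hits anywhere get
    the single pseudo-label ``Other`` with score 0.
    """
    out: dict[int, list[tuple[str, float]]] = {}
    for cidx, tags in enumerate(partition.communities()):
        size = len(tags)
        scored = []
        for cls in sorted(lexicon.classes):
            hits = len(lexicon.classes[cls] & set(tags))
            if hits:
                scored.append((cls, hits / size))
        scored.sort(key=lambda kv: (-kv[1], kv[0]))
        out[cidx] = scored if scored else [(OTHER_LABEL, 0.0)]
    return out
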