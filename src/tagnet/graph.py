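"""Undirected weighted hashtag graph.

Nodes carry a frequency (number of retained posts containing the tag);
edges carry a co-occurrence count (number of retained posts containing
both endpoints).  Edges are keyed by the lexicographically sorted pair,
so ``(u, v)`` and ``(v, u)`` are the same edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError

Pair = tuple[str, str]


def edge_key(u: str, v: str) -> Pair:
    """Canonical (sorted) key for an undirected edge."""
    if u == v:
        raise DataError(f"self-loop on node {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass
class HashtagGraph:
    area_name: str
    nodes: dict[str, int] = field(default_factory=dict)  # tag -> frequency
    edges: dict[Pair, float] = field(default_factory=dict)  # pair -> weight
    normalized_weights: dict[Pair, float] | None = None
    node_strength: dict[str, float] | None = None
    normalized_strength: dict[str, float] | None = None

    def validate(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise DataError(f"self-loop on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise DataError(f"edge ({u!r}, {v!r}) has endpoint outside nodes")
            if w <= 0:
                raise DataError(f"non-positive weight on ({u!r}, {v!r})")

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return sum(self.edges.values())

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Neighbour map ``u -> {v: weight}``; isolated nodes map to {}."""
        adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
        for (u, v), w in self.edges.items():
            adj[u][v] = w
            adj[v][u] = w
        return adj

    def strength(self) -> dict[str, float]:
        s = dict.fromkeys(self.nodes, 0.0)
        for (u, v), w in self.edges.items():
            s[u] += w
            s[v] += w
        return s

    def degree(self) -> dict[str, int]:
        d = dict.fromkeys(self.nodes, 0)
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    # -- structure -------------------------------------------------------

    def connected_components(self) -> list[list[str]]:
        """Components as sorted node lists, largest first.

        Ties on size are broken by summed incident weight (descending),
        then by smallest node label, so "the" giant component is
        deterministic.
        """
        adj = self.adjacency()
        seen: set[str] = set()
        comps: list[list[str]] = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp))

        def comp_weight(comp: list[str]) -> float:
            cs = set(comp)
            return sum(w for (u, v), w in self.edges.items() if u in cs)

        comps.sort(key=lambda c: (-len(c), -comp_weight(c), c[0]))
        return comps

    def subgraph(self, keep: set[str]) -> "HashtagGraph":
        return HashtagGraph(
            area_name=self.area_name,
            nodes={v: f for v, f in self.nodes.items() if v in keep},
            edges={
                (u, v): w for (u, v), w in self.edges.items() if u in keep and v in keep
            },
        )
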