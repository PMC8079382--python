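"""Readers and writers for the plain-text interchange formats.

Corpora travel as JSONL (one post per line) or flat CSV (hashtags
pipe-delimited); graphs as GraphML or edge-list CSV; synonym maps,
blocklists and CES lexicons as small text files.  All writers emit
deterministic byte streams (sorted keys, sorted hashtags) so identical
inputs produce identical files.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from pathlib import Path

from .corpus import Corpus, Post
from .errors import ConfigError, DataError
from .graph import HashtagGraph, edge_key

# ---------------------------------------------------------------------------
# Corpora


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.posts:
            rec = {
                "post_id": p.post_id,
                "user_id": p.user_id,
                "timestamp": p.timestamp,
                "hashtags": sorted(p.hashtags),
            }
            if p.truth_label is not None:
                rec["truth_label"] = p.truth_label
                rec["truth_topic"] = p.truth_topic
            fh.write(json.dumps(rec, sort_keys=True, ensure_ascii=False) + "\n")


def write_truth_sidecar(corpus: Corpus, path: str | Path) -> None:
    """Ground-truth labels only, one JSON object per post."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.posts:
            rec = {
                "post_id": p.post_id,
                "truth_label": p.truth_label,
                "truth_topic": p.truth_topic,
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


CSV_FIELDS = ["post_id", "user_id", "timestamp", "hashtags", "truth_label", "truth_topic"]


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_FIELDS)
        for p in corpus.posts:
            w.writerow(
                [
                    p.post_id,
                    p.user_id,
                    p.timestamp,
                    "|".join(sorted(p.hashtags)),
                    p.truth_label or "",
                    "" if p.truth_topic is None else p.truth_topic,
                ]
            )


def read_corpus(
    path: str | Path, format: str | None = None, area_name: str | None = None
) -> Corpus:
    """Read a corpus from JSONL or CSV and normalize its hashtags.

    Hashtags are lower-cased, stripped of a leading ``#``, NFKC
    Unicode-normalized; empty tags are dropped and within-post
    duplicates collapse.  Malformed records raise :class:`DataError`
    naming the line.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ConfigError(f"unknown corpus format {format!r} (expected jsonl or csv)")
    name = area_name or path.stem
    posts = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    posts.append(
                        Post(
                            post_id=str(rec["post_id"]),
                            user_id=str(rec["user_id"]),
                            timestamp=str(rec["timestamp"]),
                            hashtags=frozenset(rec["hashtags"]),
                            truth_label=rec.get("truth_label"),
                            truth_topic=rec.get("truth_topic"),
                        ).normalized()
                    )
                except (KeyError, ValueError, TypeError) as exc:
                    raise DataError(f"{path}:{lineno}: malformed record ({exc})") from exc
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, 2):
                try:
                    tags = [t for t in (rec["hashtags"] or "").split("|") if t]
                    topic = rec.get("truth_topic") or None
                    posts.append(
                        Post(
                            post_id=rec["post_id"],
                            user_id=rec["user_id"],
                            timestamp=rec["timestamp"],
                            hashtags=frozenset(tags),
                            truth_label=rec.get("truth_label") or None,
                            truth_topic=None if topic is None else int(topic),
                        ).normalized()
                    )
                except (KeyError, ValueError, TypeError) as exc:
                    raise DataError(f"{path}:{lineno}: malformed record ({exc})") from exc
    return Corpus(area_name=name, posts=posts, provenance={"kind": "file", "path": str(path)})


# ---------------------------------------------------------------------------
# Synonym maps, blocklists, lexicons


def read_synonym_csv(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``variant,canonical`` (header optional)."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["variant", "canonical"]:
                continue
            if len(row) < 2:
                raise DataError(f"{path}:{lineno}: expected 'variant,canonical'")
            entries[row[0].strip().lower()] = row[1].strip().lower()
    return entries


def write_synonym_csv(entries: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variant", "canonical"])
        for variant in sorted(entries):
            w.writerow([variant, entries[variant]])


def read_blocklist(path: str | Path) -> tuple[set[str], set[str]]:
    """Plain text, one entry per line; ``user:`` prefix marks user ids."""
    tags: set[str] = set()
    users: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            if entry.startswith("user:"):
                users.add(entry[5:].strip())
            else:
                tags.add(entry.lstrip("#").lower())
    return tags, users


def write_blocklist(tags: set[str], users: set[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in sorted(tags):
            fh.write(t + "\n")
        for u in sorted(users):
            fh.write("user:" + u + "\n")


def read_lexicon_csv(path: str | Path) -> dict[str, set[str]]:
    """CES lexicon CSV: ``class,cue-tag`` rows."""
    classes: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["class", "cue"]:
                continue
            if len(row) < 2:
                raise DataError(f"{path}:{lineno}: expected 'class,cue'")
            classes.setdefault(row[0].strip(), set()).add(row[1].strip().lower())
    return classes


# ---------------------------------------------------------------------------
# Graphs

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(graph: HashtagGraph, path: str | Path) -> None:
    """GraphML with node attrs (frequency, strength, normalized_strength)
    and edge attrs (weight, normalized_weight)."""
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    keys = [
        ("d_freq", "node", "frequency", "int"),
        ("d_strength", "node", "strength", "double"),
        ("d_nstrength", "node", "normalized_strength", "double"),
        ("d_weight", "edge", "weight", "double"),
        ("d_nweight", "edge", "normalized_weight", "double"),
    ]
    for kid, dom, name, typ in keys:
        ET.SubElement(
            root, f"{{{_GRAPHML_NS}}}key",
            id=kid, attrib={"for": dom, "attr.name": name, "attr.type": typ},
        )
    g = ET.SubElement(
        root, f"{{{_GRAPHML_NS}}}graph", id=graph.area_name or "G", edgedefault="undirected"
    )
    strengths = graph.node_strength or {}
    nstrengths = graph.normalized_strength or {}
    nweights = graph.normalized_weights or {}
    for tag in sorted(graph.nodes):
        node = ET.SubElement(g, f"{{{_GRAPHML_NS}}}node", id=tag)
        _data(node, "d_freq", graph.nodes[tag])
        if tag in strengths:
            _data(node, "d_strength", strengths[tag])
        if tag in nstrengths:
            _data(node, "d_nstrength", nstrengths[tag])
    for (u, v) in sorted(graph.edges):
        edge = ET.SubElement(g, f"{{{_GRAPHML_NS}}}edge", source=u, target=v)
        _data(edge, "d_weight", graph.edges[(u, v)])
        if (u, v) in nweights:
            _data(edge, "d_nweight", nweights[(u, v)])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _data(parent: ET.Element, key: str, value) -> None:
    el = ET.SubElement(parent, f"{{{_GRAPHML_NS}}}data", key=key)
    el.text = repr(value) if isinstance(value, float) else str(value)


def read_graphml(path: str | Path) -> HashtagGraph:
    tree = ET.parse(path)
    root = tree.getroot()
    g = root.find(f"{{{_GRAPHML_NS}}}graph")
    if g is None:
        raise DataError(f"{path}: no <graph> element")
    key_names = {
        k.get("id"): k.get("attr.name") for k in root.findall(f"{{{_GRAPHML_NS}}}key")
    }
    graph = HashtagGraph(area_name=g.get("id") or "")
    strengths: dict[str, float] = {}
    nstrengths: dict[str, float] = {}
    nweights: dict = {}
    for node in g.findall(f"{{{_GRAPHML_NS}}}node"):
        tag = node.get("id")
        attrs = _read_data(node, key_names)
        graph.nodes[tag] = int(float(attrs.get("frequency", 0)))
        if "strength" in attrs:
            strengths[tag] = float(attrs["strength"])
        if "normalized_strength" in attrs:
            nstrengths[tag] = float(attrs["normalized_strength"])
    for edge in g.findall(f"{{{_GRAPHML_NS}}}edge"):
        u, v = edge.get("source"), edge.get("target")
        attrs = _read_data(edge, key_names)
        graph.edges[edge_key(u, v)] = float(attrs.get("weight", 1.0))
        if "normalized_weight" in attrs:
            nweights[edge_key(u, v)] = float(attrs["normalized_weight"])
    if strengths:
        graph.node_strength = strengths
    if nstrengths:
        graph.normalized_strength = nstrengths
    if nweights:
        graph.normalized_weights = nweights
    graph.validate()
    return graph


def _read_data(el: ET.Element, key_names: dict) -> dict:
    out = {}
    for d in el.findall(f"{{{_GRAPHML_NS}}}data"):
        name = key_names.get(d.get("key"), d.get("key"))
        out[name] = d.text
    return out


def write_edgelist_csv(graph: HashtagGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "weight"])
        for (u, v) in sorted(graph.edges):
            w.writerow([u, v, graph.edges[(u, v)]])
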