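"""End-to-end orchestration: simulate -> clean -> network -> centrality
-> communities -> merge, from a single YAML config.

Every artefact is written deterministically (sorted keys, canonical
float repr), and each run leaves a manifest with a hash of the resolved
configuration so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .centrality import (
    betweenness_centrality,
    degree_and_strength,
    edge_betweenness,
    eigenvector_centrality,
)
from .cleaning import Blocklist, SynonymMap, clean
from .communities import CESLexicon, fast_greedy_communities, suggest_ces_labels
from .corpus import Corpus
from .errors import ConfigError
from .graph import HashtagGraph
from .merged import bridge_hashtags, merge_graphs, merged_eigenvector
from .network import (
    build_cooccurrence_graph,
    cooccurrence_coverage,
    hashtag_frequencies,
    normalize_strength,
    select_top_hashtags,
)
from .synthetic import GeneratorConfig, generate_corpus

log = logging.getLogger("tagnet")

MIN_POSTS_FLOOR = 1000  # warn below this corpus size


def default_lexicon() -> CESLexicon:
    ref = importlib.resources.files("tagnet.data").joinpath("ces_lexicon.csv")
    with importlib.resources.as_file(ref) as path:
        return CESLexicon(tio.read_lexicon_csv(path))


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    top_hashtags: int = 150
    top_pairs: int = 1400
    synthetic: GeneratorConfig | None = None
    file_areas: list[dict] = field(default_factory=list)  # {name, path, format}
    synonyms_path: Path | None = None
    blocklist_path: Path | None = None
    lexicon_path: Path | None = None
    detector: dict = field(default_factory=dict)
    centrality: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")
        d = dict(d)
        if "out_dir" not in d:
            raise ConfigError("config missing required field 'out_dir'")
        synth = d.get("synthetic")
        gen = None
        if synth is not None:
            synth = dict(synth)
            synth.setdefault("seed", d.get("seed", 0))
            gen = GeneratorConfig.from_dict(synth)
        cfg = cls(
            out_dir=Path(d["out_dir"]),
            seed=int(d.get("seed", 0)),
            top_hashtags=int(d.get("top_hashtags", 150)),
            top_pairs=int(d.get("top_pairs", 1400)),
            synthetic=gen,
            file_areas=list(d.get("areas", [])),
            synonyms_path=_resolve(d.get("synonyms"), base),
            blocklist_path=_resolve(d.get("blocklist"), base),
            lexicon_path=_resolve(d.get("lexicon"), base),
            detector=dict(d.get("detector", {})),
            centrality=dict(d.get("centrality", {})),
        )
        if cfg.top_hashtags < 1:
            raise ConfigError(f"top_hashtags must be >= 1, got {cfg.top_hashtags}")
        if cfg.top_pairs < 1:
            raise ConfigError(f"top_pairs must be >= 1, got {cfg.top_pairs}")
        if cfg.synthetic is None and not cfg.file_areas:
            raise ConfigError("config needs a 'synthetic' block or an 'areas' list")
        # fail fast on unresolvable inputs, before any computation
        for name in ("synonyms_path", "blocklist_path", "lexicon_path"):
            p = getattr(cfg, name)
            if p is not None and not p.exists():
                raise ConfigError(f"{name.replace('_path', '')} file not found: {p}")
        for a in cfg.file_areas:
            if not Path(a["path"]).exists():
                raise ConfigError(f"area corpus not found: {a['path']}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh), base=path.parent)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "top_hashtags": self.top_hashtags,
            "top_pairs": self.top_pairs,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "areas": self.file_areas,
            "detector": self.detector,
            "centrality": self.centrality,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def area_sources(self) -> list[dict]:
        out = []
        if self.synthetic is not None:
            for i in range(self.synthetic.n_areas):
                out.append({"kind": "synthetic", "area_index": i})
        for a in self.file_areas:
            out.append({"kind": "file", **a})
        return out


def _resolve(p, base: Path):
    if p is None:
        return None
    p = Path(p)
    return p if p.is_absolute() else base / p


def _load_corpus(config: PipelineConfig, source: dict) -> Corpus:
    if source["kind"] == "synthetic":
        return generate_corpus(config.synthetic, source["area_index"])
    return tio.read_corpus(
        source["path"], format=source.get("format"), area_name=source.get("name")
    )


def _cleaning_inputs(config: PipelineConfig) -> tuple[Blocklist, SynonymMap]:
    tags: set[str] = set()
    users: set[str] = set()
    entries: dict[str, str] = {}
    if config.synthetic is not None:
        # synthetic ads carry known blocklisted tags and the generator's
        # registered misspellings define the synonym merges
        tags |= {t.lower() for t in config.synthetic.ad_tags}
        entries.update(SynonymMap.from_groups(config.synthetic.synonym_groups).entries)
    if config.blocklist_path is not None:
        t, u = tio.read_blocklist(config.blocklist_path)
        tags |= t
        users |= u
    if config.synonyms_path is not None:
        entries.update(tio.read_synonym_csv(config.synonyms_path))
    return Blocklist(tags, users), SynonymMap(entries)


def _lexicon(config: PipelineConfig) -> CESLexicon:
    if config.lexicon_path is not None:
        return CESLexicon(tio.read_lexicon_csv(config.lexicon_path))
    return default_lexicon()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_area(config: PipelineConfig, source: dict) -> dict:
    """Run the full per-area pipeline and write artefacts under
    ``out_dir/<area>/``; returns a result dict with in-memory objects."""
    corpus = _load_corpus(config, source)
    area = corpus.area_name
    out = config.out_dir / area
    out.mkdir(parents=True, exist_ok=True)
    log.info("[%s] %d posts in", area, len(corpus))

    if len(corpus) < MIN_POSTS_FLOOR:
        warnings.warn(
            f"corpus {area!r} has {len(corpus)} posts, below the "
            f"{MIN_POSTS_FLOOR}-post floor",
            stacklevel=2,
        )

    tio.write_corpus_jsonl(corpus, out / "corpus_raw.jsonl")
    blocklist, synonym_map = _cleaning_inputs(config)
    cleaned, report = clean(corpus, blocklist, synonym_map, **config.detector)
    log.info(
        "[%s] retained %d/%d (discard %.1f%%)",
        area, report.n_retained, report.n_input, 100 * report.discard_fraction,
    )
    tio.write_corpus_jsonl(cleaned, out / "corpus_clean.jsonl")
    _json_dump(report.to_dict(), out / "cleaning_report.json")

    freqs = hashtag_frequencies(cleaned)
    query_tag = corpus.provenance.get("query_tag", area)
    selected = select_top_hashtags(freqs, n=config.top_hashtags, exclude={query_tag})
    graph = build_cooccurrence_graph(cleaned, selected)
    graph = normalize_strength(graph)
    coverage = cooccurrence_coverage(cleaned, selected)
    tio.write_graphml(graph, out / "graph.graphml")
    tio.write_edgelist_csv(graph, out / "edges.csv")

    cpar = dict(config.centrality)
    mode = cpar.pop("mode", "inverse_weight")
    eig = eigenvector_centrality(graph, **cpar)
    btw = betweenness_centrality(graph, mode=mode)
    ebtw = edge_betweenness(graph, mode=mode)
    deg, stren = degree_and_strength(graph)
    _write_node_scores(out / "centrality.csv", [eig, btw, deg, stren])
    _write_edge_scores(out / "edge_betweenness.csv", ebtw)

    partition = fast_greedy_communities(graph)
    lexicon = _lexicon(config)
    labels = suggest_ces_labels(partition, lexicon, graph)
    _write_membership(out / "communities.csv", partition, labels)
    _json_dump(
        {
            "dendrogram": [[a, b, q] for a, b, q in partition.dendrogram],
            "cut_index": partition.cut_index,
            "modularity": partition.modularity,
            "n_communities": partition.n_communities,
        },
        out / "dendrogram.json",
    )

    manifest = {
        "area": area,
        "source": {k: str(v) for k, v in source.items()},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["simulate/load", "clean", "network", "centrality", "communities"],
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "coverage": coverage,
    }
    _json_dump(manifest, out / "manifest.json")

    return {
        "area": area,
        "corpus": cleaned,
        "report": report,
        "graph": graph,
        "coverage": coverage,
        "eigenvector": eig,
        "betweenness": btw,
        "edge_betweenness": ebtw,
        "degree": deg,
        "strength": stren,
        "partition": partition,
        "ces_labels": labels,
    }


def run_all(config: PipelineConfig) -> dict:
    """Per-area runs, cross-area merge, and a summary table."""
    sources = config.area_sources()
    if not sources:
        raise ConfigError("no areas configured")
    results = [run_area(config, s) for s in sources]

    graphs: list[HashtagGraph] = [r["graph"] for r in results]
    merged = merge_graphs(graphs, n_pairs=config.top_pairs)
    mout = config.out_dir / "merged"
    mout.mkdir(parents=True, exist_ok=True)
    tio.write_graphml(normalize_strength(merged.underlying), mout / "graph.graphml")
    eig = merged_eigenvector(merged, **{
        k: v for k, v in config.centrality.items() if k != "mode"
    })
    _write_node_scores(mout / "eigenvector.csv", [eig])
    bridges = bridge_hashtags(merged)
    pd.DataFrame(bridges).to_csv(mout / "bridges.csv", index=False)
    _json_dump(
        {
            "n_nodes": merged.underlying.n_nodes,
            "n_edges": merged.underlying.n_edges,
            "linkage_coverage": merged.linkage_coverage,
            "top_pairs": config.top_pairs,
            "config_hash": config.config_hash(),
        },
        mout / "merged_report.json",
    )

    rows = []
    for r in results:
        top5 = sorted(
            r["eigenvector"].node_scores,
            key=lambda t: (-r["eigenvector"].node_scores[t], t),
        )[:5]
        rows.append(
            {
                "area": r["area"],
                "n_retained": r["report"].n_retained,
                "discard_fraction": r["report"].discard_fraction,
                "n_nodes": r["graph"].n_nodes,
                "n_edges": r["graph"].n_edges,
                "coverage": r["coverage"],
                "n_communities": r["partition"].n_communities,
                "modularity": r["partition"].modularity,
                "top5_eigenvector": "|".join(top5),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(config.out_dir / "summary.csv", index=False)
    return {"areas": results, "merged": merged, "summary": summary}


def _write_node_scores(path: Path, scores_list) -> None:
    rows = []
    for sc in scores_list:
        for tag in sorted(sc.node_scores or {}):
            rows.append(
                {
                    "hashtag": tag,
                    "measure": sc.measure,
                    "raw": sc.node_scores[tag],
                    "normalized": (sc.node_scores_normalized or {}).get(tag, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_membership(path: Path, partition, labels) -> None:
    rows = []
    for tag in sorted(partition.membership):
        c = partition.membership[tag]
        cls, score = labels[c][0]
        rows.append({"hashtag": tag, "community": c, "ces_label": cls, "ces_score": score})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_edge_scores(path: Path, sc) -> None:
    rows = []
    for (u, v) in sorted(sc.edge_scores or {}):
        rows.append(
            {
                "source": u,
                "target": v,
                "measure": sc.measure,
                "raw": sc.edge_scores[(u, v)],
                "normalized": (sc.edge_scores_normalized or {}).get((u, v), ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
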