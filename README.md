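# tagnet

Hashtag co-occurrence network analysis of social-media discourse around
natural areas. The package provides a reproducible pipeline:

1. **simulate** — synthetic per-area post corpora with planted ground
   truth (Zipf-distributed hashtags, topic structure, bot templates,
   advertising posts, misspelling variants), standing in for hashtag-query
   downloads that are no longer retrievable;
2. **clean** — automated-post detection (near-duplicate Jaccard graph,
   optional volume-anomaly and burst detectors), blocklist filtering,
   synonym/misspelling merging, with a discard-accounting report;
3. **network** — per-area weighted co-occurrence graph over the top-150
   hashtags (query tag excluded), with strength normalization and a
   co-occurrence coverage diagnostic;
4. **centrality** — eigenvector centrality (power iteration), Brandes
   node and edge betweenness (unweighted or inverse-weight distances),
   degree and strength — all implemented from scratch, with an exact
   rational-arithmetic mode for oracle comparisons;
5. **communities** — Clauset–Newman–Moore fast-greedy modularity
   agglomeration with deterministic tie-breaking, plus lexicon-based
   cultural-ecosystem-services (CES) label suggestions;
6. **merge** — cross-area network from the most frequent hashtag pairs
   (1400 by default), with bridge-hashtag ranking (betweenness, area
   reach, articulation points).

## CLI

```sh
tagnet simulate --config gen.yaml --seed 1 --out corpora/
tagnet clean --in corpora/area00.jsonl --synonyms syn.csv \
    --blocklist block.txt --out clean.jsonl --report report.json
tagnet network --in clean.jsonl --top 150 --out area00.graphml
tagnet centrality --graph area00.graphml \
    --measures eigenvector,betweenness,edge_betweenness --out scores.csv
tagnet communities --graph area00.graphml --out comm/
tagnet merge --graphs a.graphml --graphs b.graphml --top-pairs 1400 --out merged/
tagnet run-all --config pipeline.yaml --seed 1
```

A minimal `pipeline.yaml`:

```yaml
out_dir: out
seed: 1
top_hashtags: 150
top_pairs: 1400
synthetic:
  n_areas: 14
  posts_per_area: 2000
```

File-based corpora can be supplied instead of (or alongside) the
synthetic block:

```yaml
areas:
  - {name: myarea, path: myarea.jsonl, format: jsonl}
```

Corpora are JSONL (one post per line: `post_id`, `user_id`,
`timestamp`, `hashtags`, optional truth fields) or flat CSV with
pipe-delimited hashtags. Graphs are exported as GraphML (readable by
networkx/igraph/Gephi) and edge-list CSV. Synonym maps are two-column
CSV (`variant,canonical`); blocklists are plain text with a `user:`
prefix for user ids; the CES lexicon is a `class,cue` CSV (a default
ships with the package).

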