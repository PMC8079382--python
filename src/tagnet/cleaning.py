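"""Corpus filtering: automated-post detection, blocklisting, tag merging.

The detector suite mirrors three complementary signals: near-duplicate
content (a post-similarity graph over hashtag-set Jaccard), per-user
volume anomalies, and per-user temporal bursts.  The graph-based
detector runs first and is normally sufficient on its own; the other
two are opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

from .corpus import Corpus, Post
from .errors import ConfigError

DISCARD_WARN_FRACTION = 0.25  # observed ceiling for discards; warn above it


@dataclass
class SynonymMap:
    """variant tag -> canonical tag; must be idempotent."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for variant, canonical in self.entries.items():
            if canonical in self.entries and self.entries[canonical] != canonical:
                raise ConfigError(
                    f"synonym map not idempotent: {variant!r} -> {canonical!r} "
                    f"-> {self.entries[canonical]!r}"
                )

    def canonical(self, tag: str) -> str:
        return self.entries.get(tag, tag)

    @classmethod
    def from_groups(cls, groups: dict[str, list[str]]) -> "SynonymMap":
        """Build from canonical -> [variants] groups (generator convention)."""
        entries = {}
        for canonical, variants in groups.items():
            for v in variants:
                entries[v] = canonical
        return cls(entries)


@dataclass
class Blocklist:
    banned_hashtags: set[str] = field(default_factory=set)
    banned_users: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.banned_hashtags = {t for t in self.banned_hashtags if t}
        self.banned_users = {u for u in self.banned_users if u}

    def matches(self, post: Post) -> bool:
        return post.user_id in self.banned_users or bool(
            self.banned_hashtags & post.hashtags
        )


@dataclass
class CleaningReport:
    n_input: int
    n_flagged_bot: int
    n_flagged_blocklist: int
    n_retained: int
    discard_fraction: float
    per_detector_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_retained + self.n_flagged_bot + self.n_flagged_blocklist == self.n_input
        if self.n_input:
            assert abs(self.discard_fraction - (1 - self.n_retained / self.n_input)) < 1e-12

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_flagged_bot": self.n_flagged_bot,
            "n_flagged_blocklist": self.n_flagged_blocklist,
            "n_retained": self.n_retained,
            "discard_fraction": self.discard_fraction,
            "per_detector_counts": dict(sorted(self.per_detector_counts.items())),
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Detectors


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _near_duplicate_posts(
    posts: list[Post], jaccard_threshold: float, min_cluster: int
) -> set[str]:
    """Graph-based detector: connected components of the Jaccard graph.

    Candidate pairs come from prefix filtering: order each post's tags
    by ascending document frequency; two sets with Jaccard >= t must
    share a token among the first ``len - ceil(t*len) + 1`` rarest ones.
    This keeps the pair search near-linear on organic corpora where the
    only universally shared tags (e.g. the query tag) are frequent.
    """
    n = len(posts)
    df: dict[str, int] = {}
    for p in posts:
        for tag in p.hashtags:
            df[tag] = df.get(tag, 0) + 1
    ordered = [sorted(p.hashtags, key=lambda t: (df[t], t)) for p in posts]

    index: dict[str, list[int]] = {}
    candidates: set[tuple[int, int]] = set()
    for i, tags in enumerate(ordered):
        k = len(tags)
        if k == 0:
            continue
        prefix_len = k - math.ceil(jaccard_threshold * k) + 1
        for tag in tags[:prefix_len]:
            for j in index.get(tag, ()):
                candidates.add((j, i))
            index.setdefault(tag, []).append(i)

    uf = _UnionFind(n)
    for i, j in candidates:
        if _jaccard(posts[i].hashtags, posts[j].hashtags) >= jaccard_threshold:
            uf.union(i, j)

    comp_sizes: dict[int, int] = {}
    for i in range(n):
        r = uf.find(i)
        comp_sizes[r] = comp_sizes.get(r, 0) + 1
    return {
        posts[i].post_id
        for i in range(n)
        if comp_sizes[uf.find(i)] >= min_cluster
    }


def _volume_anomaly_users(posts: list[Post], rate_zscore: float) -> set[str]:
    counts: dict[str, int] = {}
    for p in posts:
        counts[p.user_id] = counts.get(p.user_id, 0) + 1
    if len(counts) < 2:
        return set()
    vals = list(counts.values())
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    return {u for u, c in counts.items() if c > mean + rate_zscore * sd}


def _parse_ts(ts: str) -> float:
    return datetime.fromisoformat(ts.replace("Z", "+00:00")).timestamp()


def _bursty_users(
    posts: list[Post], rate_window: float, rate_zscore: float, min_posts: int = 5
) -> set[str]:
    """Time-series detector: a user is bursty when one window holds more
    posts than mean + z*sd of that user's own windowed counts."""
    if not posts:
        return set()
    times: dict[str, list[float]] = {}
    for p in posts:
        times.setdefault(p.user_id, []).append(_parse_ts(p.timestamp))
    t0 = min(min(v) for v in times.values())
    t1 = max(max(v) for v in times.values())
    n_bins = max(2, int((t1 - t0) / rate_window) + 1)
    flagged = set()
    for user, ts in times.items():
        if len(ts) < min_posts:
            continue
        bins = [0] * n_bins
        for t in ts:
            bins[min(n_bins - 1, int((t - t0) / rate_window))] += 1
        mean = sum(bins) / n_bins
        sd = math.sqrt(sum((b - mean) ** 2 for b in bins) / n_bins)
        if max(bins) > mean + rate_zscore * sd:
            flagged.add(user)
    return flagged


def detect_automated_posts(
    corpus: Corpus,
    jaccard_threshold: float = 0.7,
    min_cluster: int = 3,
    rate_window: float = 3600.0,
    rate_zscore: float = 3.0,
    use_anomaly: bool = False,
    use_timeseries: bool = False,
) -> tuple[set[str], dict[str, int]]:
    """Flag automated posts; returns (post ids, per-detector counts).

    The graph-based near-duplicate detector always runs; the volume
    anomaly and burst detectors are optional refinements.
    """
    if not (0 < jaccard_threshold <= 1):
        raise ConfigError(f"jaccard_threshold must be in (0, 1], got {jaccard_threshold}")
    if min_cluster < 2:
        raise ConfigError(f"min_cluster must be >= 2, got {min_cluster}")
    posts = corpus.posts
    per_detector: dict[str, int] = {}

    graph_flagged = _near_duplicate_posts(posts, jaccard_threshold, min_cluster)
    per_detector["graph"] = len(graph_flagged)
    flagged = set(graph_flagged)

    if use_anomaly:
        users = _volume_anomaly_users(posts, rate_zscore)
        ids = {p.post_id for p in posts if p.user_id in users}
        per_detector["anomaly"] = len(ids)
        flagged |= ids
    if use_timeseries:
        users = _bursty_users(posts, rate_window, rate_zscore)
        ids = {p.post_id for p in posts if p.user_id in users}
        per_detector["timeseries"] = len(ids)
        flagged |= ids
    return flagged, per_detector


# ---------------------------------------------------------------------------
# Blocklist and synonym application


def apply_blocklist(corpus: Corpus, blocklist: Blocklist) -> tuple[Corpus, int]:
    kept = [p for p in corpus.posts if not blocklist.matches(p)]
    removed = len(corpus.posts) - len(kept)
    return Corpus(corpus.area_name, kept, corpus.provenance), removed


def apply_synonym_map(corpus: Corpus, synonym_map: SynonymMap) -> Corpus:
    synonym_map.validate()
    posts = []
    for p in corpus.posts:
        merged = frozenset(synonym_map.canonical(t) for t in p.hashtags)
        posts.append(
            Post(p.post_id, p.user_id, p.timestamp, merged, p.truth_label, p.truth_topic)
        )
    return Corpus(corpus.area_name, posts, corpus.provenance)


# ---------------------------------------------------------------------------
# Orchestration


def clean(
    corpus: Corpus,
    blocklist: Blocklist | None = None,
    synonym_map: SynonymMap | None = None,
    jaccard_threshold: float = 0.7,
    min_cluster: int = 3,
    rate_window: float = 3600.0,
    rate_zscore: float = 3.0,
    use_anomaly: bool = False,
    use_timeseries: bool = False,
) -> tuple[Corpus, CleaningReport]:
    """Normalize, drop automated posts, blocklist, merge synonyms.

    Every input post ends up exactly one of retained / bot-flagged /
    blocklist-removed; a warning is appended when the overall discard
    fraction exceeds 25%.
    """
    blocklist = blocklist or Blocklist()
    synonym_map = synonym_map or SynonymMap()
    n_input = len(corpus)

    normalized = corpus.normalized()
    flagged, per_detector = detect_automated_posts(
        normalized,
        jaccard_threshold=jaccard_threshold,
        min_cluster=min_cluster,
        rate_window=rate_window,
        rate_zscore=rate_zscore,
        use_anomaly=use_anomaly,
        use_timeseries=use_timeseries,
    )
    survivors = Corpus(
        normalized.area_name,
        [p for p in normalized.posts if p.post_id not in flagged],
        normalized.provenance,
    )
    survivors, n_blocked = apply_blocklist(survivors, blocklist)
    cleaned = apply_synonym_map(survivors, synonym_map)

    n_retained = len(cleaned)
    discard_fraction = 0.0 if n_input == 0 else 1.0 - n_retained / n_input
    warnings = []
    if discard_fraction > DISCARD_WARN_FRACTION:
        warnings.append(
            f"discard fraction {discard_fraction:.3f} exceeds "
            f"{DISCARD_WARN_FRACTION:.0%} of input posts"
        )
    report = CleaningReport(
        n_input=n_input,
        n_flagged_bot=len(flagged),
        n_flagged_blocklist=n_blocked,
        n_retained=n_retained,
        discard_fraction=discard_fraction,
        per_detector_counts=per_detector,
        warnings=warnings,
    )
    report.validate()
    return cleaned, report
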