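"""Synthetic social-media corpus generator with planted ground truth.

Stands in for hashtag-query downloads that are no longer retrievable.
Each area gets disjoint per-topic vocabularies plus a shared global
vocabulary of travel/nature/photo-style tags; organic posts mix the two
under a Zipf rank-frequency law, bot posts replicate per-user templates
in one-hour bursts, and ad posts carry blocklisted tags.  Everything is
a pure function of ``(config, area_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np

from .corpus import Corpus, Post
from .errors import ConfigError

EPOCH = datetime(2019, 1, 1, tzinfo=timezone.utc)

# Curated head of the shared vocabulary: high-rank global tags that recur
# across areas and act as cross-area connectors in the merged network.
_SHARED_HEAD = [
    "travel", "nature", "photo", "travelphotography", "wanderlust",
    "adventure", "photography", "ocean", "island", "sunset", "beach",
    "wildlife", "landscape", "holiday", "sea", "sun", "relax", "happy",
    "summer", "paradise", "hiking", "birds", "whales", "diving", "reef",
    "luxury", "art", "food", "music", "sky", "naturelovers", "vacation",
    "explore", "instagood", "beautiful", "trip", "outdoors", "coast",
    "sand", "waves",
]

DEFAULT_SYNONYM_GROUPS = {
    "travel": ["travell", "travelgram", "instatravel", "igtravel"],
    "nature": ["naturegram", "nature_perfection"],
    "photography": ["photografy", "photographyy"],
}

DEFAULT_AD_TAGS = ["chocolate", "shoponline", "promo", "discount"]


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic corpus generator."""

    n_areas: int = 14
    posts_per_area: int = 2000
    vocab_size_per_topic: int = 300
    n_topics: int = 5
    shared_vocab_size: int = 300
    zipf_exponent: float = 1.1
    tags_min: int = 3
    tags_lambda: float = 6.0
    p_topic: float = 0.5
    bot_fraction: float = 0.05
    bot_template_size: int = 10
    bot_jitter: float = 0.05
    ad_fraction: float = 0.02
    ad_tags: list[str] = field(default_factory=lambda: list(DEFAULT_AD_TAGS))
    misspelling_rate: float = 0.02
    synonym_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SYNONYM_GROUPS.items()}
    )
    n_bot_users: int = 3
    organic_user_pool: int = 800
    time_span_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_topic", "bot_fraction", "bot_jitter", "ad_fraction",
                     "misspelling_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.bot_fraction + self.ad_fraction > 1.0:
            raise ConfigError(
                "bot_fraction + ad_fraction must not exceed 1, got "
                f"{self.bot_fraction + self.ad_fraction}"
            )
        if self.zipf_exponent <= 0:
            raise ConfigError(f"zipf_exponent must be > 0, got {self.zipf_exponent}")
        for name in ("n_areas", "posts_per_area", "vocab_size_per_topic", "n_topics",
                     "shared_vocab_size", "bot_template_size", "n_bot_users",
                     "organic_user_pool", "time_span_days"):
            v = getattr(self, name)
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.tags_min < 0:
            raise ConfigError(f"tags_min must be >= 0, got {self.tags_min}")
        if self.tags_lambda < 0:
            raise ConfigError(f"tags_lambda must be >= 0, got {self.tags_lambda}")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        tpp = d.pop("tags_per_post", None)
        if tpp is not None:
            d["tags_min"] = tpp.get("min", 3)
            d["tags_lambda"] = tpp.get("lambda", 6.0)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown generator config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }


def area_name(area_index: int) -> str:
    return f"area{area_index:02d}"


def zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def shared_vocabulary(config: GeneratorConfig) -> list[str]:
    """Global vocabulary shared by all areas, in Zipf rank order."""
    vocab = list(_SHARED_HEAD[: config.shared_vocab_size])
    k = len(vocab)
    vocab.extend(f"shared{i:04d}" for i in range(k, config.shared_vocab_size))
    return vocab


def topic_vocabulary(area_index: int, topic: int, size: int) -> list[str]:
    """Per-area, per-topic vocabulary; disjoint across areas and topics."""
    return [f"a{area_index:02d}t{topic}x{r:04d}" for r in range(size)]


def _iso(ts: datetime) -> str:
    return ts.strftime("%Y-%m-%dT%H:%M:%SZ")


def generate_corpus(config: GeneratorConfig, area_index: int) -> Corpus:
    """Generate one area's corpus with ground-truth labels.

    Deterministic: identical ``(config, area_index)`` yields an identical
    corpus.  The area's query tag is inserted into every post (all
    downloaded posts contain the query term by construction); it is
    excluded from analysis graphs downstream.
    """
    config.validate()
    if not (0 <= area_index < config.n_areas):
        raise ConfigError(
            f"area_index must be in [0, {config.n_areas}), got {area_index}"
        )
    rng = np.random.default_rng([int(config.seed), int(area_index), 0x7A67])
    name = area_name(area_index)

    shared = shared_vocabulary(config)
    shared_p = zipf_probs(len(shared), config.zipf_exponent)
    topics = [
        topic_vocabulary(area_index, t, config.vocab_size_per_topic)
        for t in range(config.n_topics)
    ]
    topic_p = zipf_probs(config.vocab_size_per_topic, config.zipf_exponent)

    tag_topics: dict[str, int] = {}
    for t, vocab in enumerate(topics):
        for tag in vocab:
            tag_topics[tag] = t

    # Bot users: fixed templates drawn from the shared vocabulary, and a
    # handful of one-hour burst windows each.
    bot_templates = []
    bot_windows = []
    span_seconds = config.time_span_days * 86400
    for _ in range(config.n_bot_users):
        size = min(config.bot_template_size, len(shared))
        tmpl = list(rng.choice(shared, size=size, replace=False, p=shared_p))
        bot_templates.append(tmpl)
        n_windows = max(1, config.posts_per_area // 500)
        bot_windows.append(rng.integers(0, max(1, span_seconds - 3600), size=n_windows))

    def misspell(tag: str) -> str:
        variants = config.synonym_groups.get(tag)
        if variants and rng.random() < config.misspelling_rate:
            return variants[int(rng.integers(len(variants)))]
        return tag

    posts: list[Post] = []
    for i in range(config.posts_per_area):
        r = rng.random()
        if r < config.bot_fraction:
            label = "bot"
        elif r < config.bot_fraction + config.ad_fraction:
            label = "ad"
        else:
            label = "organic"

        if label == "organic":
            topic = int(rng.integers(config.n_topics))
            n_tags = config.tags_min + int(rng.poisson(config.tags_lambda))
            tags: set[str] = set()
            for _ in range(n_tags):
                if rng.random() < config.p_topic:
                    tag = topics[topic][
                        int(rng.choice(config.vocab_size_per_topic, p=topic_p))
                    ]
                else:
                    tag = shared[int(rng.choice(len(shared), p=shared_p))]
                tags.add(misspell(tag))
            user = f"u{int(rng.integers(config.organic_user_pool)):05d}"
            ts = EPOCH + timedelta(seconds=float(rng.uniform(0, span_seconds)))
            truth_topic: int | None = topic
        elif label == "bot":
            b = int(rng.integers(config.n_bot_users))
            tags = set()
            for tag in bot_templates[b]:
                if rng.random() < config.bot_jitter:
                    tag = shared[int(rng.choice(len(shared), p=shared_p))]
                tags.add(tag)
            user = f"bot{b:03d}"
            w0 = float(bot_windows[b][int(rng.integers(len(bot_windows[b])))])
            ts = EPOCH + timedelta(seconds=w0 + float(rng.uniform(0, 3600)))
            truth_topic = None
        else:  # ad
            n_ad = 1 + int(rng.integers(min(2, len(config.ad_tags))))
            tags = set(rng.choice(config.ad_tags, size=n_ad, replace=False))
            n_extra = 2 + int(rng.poisson(2.0))
            for _ in range(n_extra):
                tags.add(shared[int(rng.choice(len(shared), p=shared_p))])
            user = f"ad{int(rng.integers(20)):03d}"
            ts = EPOCH + timedelta(seconds=float(rng.uniform(0, span_seconds)))
            truth_topic = None

        tags.add(name)  # the query tag appears in every downloaded post
        posts.append(
            Post(
                post_id=f"{name}-{i:06d}",
                user_id=user,
                timestamp=_iso(ts),
                hashtags=frozenset(tags),
                truth_label=label,
                truth_topic=truth_topic,
            )
        )

    return Corpus(
        area_name=name,
        posts=posts,
        provenance={
            "kind": "synthetic",
            "seed": config.seed,
            "area_index": area_index,
            "config": config.to_dict(),
            "tag_topics": tag_topics,
            "query_tag": name,
        },
    )


def corpus_summary(corpus: Corpus) -> dict:
    """Per-label post counts and a canonical hashtag frequency histogram."""
    label_counts = {"organic": 0, "bot": 0, "ad": 0, "unlabelled": 0}
    freqs: dict[str, int] = {}
    for post in corpus:
        key = post.truth_label if post.truth_label is not None else "unlabelled"
        label_counts[key] += 1
        for tag in post.hashtags:
            freqs[tag] = freqs.get(tag, 0) + 1
    assert sum(label_counts.values()) == len(corpus)
    return {
        "area_name": corpus.area_name,
        "n_posts": len(corpus),
        "label_counts": label_counts,
        "hashtag_frequencies": dict(sorted(freqs.items())),
    }


def fitted_zipf_slope(
    freqs: dict[str, int],
    max_rank: int | None = None,
    min_rank: int = 1,
) -> float:
    """Least-squares slope of log(frequency) vs log(rank).

    Used to check that generated marginals follow the configured Zipf
    law; the slope should sit near ``-zipf_exponent``.  ``min_rank``
    lets callers skip the saturated head (a tag counts at most once per
    post, so post-level counts of the very top ranks flatten), and
    ``max_rank`` the noisy tail.
    """
    counts = sorted(freqs.values(), reverse=True)
    if max_rank is not None:
        counts = counts[:max_rank]
    counts = [c for c in counts if c > 0]
    ranks = range(1, len(counts) + 1)
    pairs = [(r, c) for r, c in zip(ranks, counts) if r >= min_rank]
    if len(pairs) < 2:
        raise ValueError("need at least two ranked frequencies")
    x = np.log(np.array([r for r, _ in pairs], dtype=float))
    y = np.log(np.array([c for _, c in pairs], dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return slope
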