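"""Core corpus types: posts, corpora, and hashtag normalization.

A :class:`Post` is one social-media record reduced to the fields the
analysis needs: an opaque post id, an anonymised user id, a timestamp and
a set of hashtags.  Synthetic posts additionally carry ground-truth
labels (``organic`` / ``bot`` / ``ad``) and, for organic posts, the
planted topic index.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import DataError

TRUTH_LABELS = ("organic", "bot", "ad")


def normalize_tag(tag: str) -> str:
    """Canonicalize a single hashtag.

    Lower-cases, strips a leading ``#`` and surrounding whitespace, and
    applies Unicode NFKC normalization.  May return the empty string,
    which callers drop.
    """
    tag = unicodedata.normalize("NFKC", tag).strip().lstrip("#").strip()
    return tag.lower()


def normalize_hashtags(tags: Iterable[str]) -> frozenset[str]:
    """Normalize a collection of raw hashtags into a deduplicated set."""
    out = set()
    for t in tags:
        n = normalize_tag(t)
        if n:
            out.add(n)
    return frozenset(out)


@dataclass(frozen=True)
class Post:
    """One social-media record."""

    post_id: str
    user_id: str
    timestamp: str  # ISO-8601
    hashtags: frozenset[str]
    truth_label: str | None = None  # organic | bot | ad, synthetic only
    truth_topic: int | None = None

    def __post_init__(self):
        if self.truth_label is not None and self.truth_label not in TRUTH_LABELS:
            raise DataError(
                f"truth_label must be one of {TRUTH_LABELS}, got {self.truth_label!r}"
            )

    def normalized(self) -> "Post":
        return replace(self, hashtags=normalize_hashtags(self.hashtags))


@dataclass
class Corpus:
    """An ordered collection of posts for one area."""

    area_name: str
    posts: list[Post]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.post_id for p in self.posts]
        if len(ids) != len(set(ids)):
            raise DataError(f"duplicate post_id in corpus {self.area_name!r}")

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    def normalized(self) -> "Corpus":
        """Return a copy with every post's hashtags normalized."""
        return Corpus(
            area_name=self.area_name,
            posts=[p.normalized() for p in self.posts],
            provenance=self.provenance,
        )

    def is_synthetic(self) -> bool:
        return self.provenance.get("kind") == "synthetic"
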