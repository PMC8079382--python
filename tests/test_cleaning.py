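import pytest

from conftest import make_corpus, make_post
from tagnet.cleaning import (
    Blocklist,
    SynonymMap,
    apply_blocklist,
    apply_synonym_map,
    clean,
    detect_automated_posts,
)
from tagnet.corpus import Corpus
from tagnet.errors import ConfigError
from tagnet.synthetic import GeneratorConfig, generate_corpus


class TestSynonymMap:
    def test_non_idempotent_rejected(self):
        with pytest.raises(ConfigError, match="idempotent"):
            SynonymMap({"a": "b", "b": "c"})

    def test_identity_entries_allowed(self):
        SynonymMap({"travelgram": "travel", "travel": "travel"})

    def test_paper_example_merge(self):
        m = SynonymMap({"travelgram": "travel", "instatravel": "travel"})
        corpus = make_corpus([{"travelgram", "instatravel", "beach"}])
        out = apply_synonym_map(corpus, m)
        assert out.posts[0].hashtags == {"travel", "beach"}

    def test_empty_map_is_identity(self):
        corpus = make_corpus([{"a", "b"}, {"c"}])
        out = apply_synonym_map(corpus, SynonymMap())
        assert [p.hashtags for p in out] == [p.hashtags for p in corpus]

    def test_set_collapse_after_merge(self):
        out = apply_synonym_map(
            make_corpus([{"travell", "travel"}]), SynonymMap({"travell": "travel"})
        )
        assert out.posts[0].hashtags == {"travel"}

    def test_never_increases_distinct_tags(self):
        corpus = make_corpus([{"a", "b", "x"}, {"c", "x"}, {"b"}])
        m = SynonymMap({"a": "c", "x": "b"})
        before = {t for p in corpus for t in p.hashtags}
        after = {t for p in apply_synonym_map(corpus, m) for t in p.hashtags}
        assert len(after) <= len(before)


class TestBlocklist:
    def test_banned_tag_removes_post(self):
        corpus = make_corpus([{"rapanui", "chocolate"}])
        out, removed = apply_blocklist(corpus, Blocklist({"chocolate"}, set()))
        assert removed == 1 and len(out) == 0

    def test_banned_user_removes_post(self):
        posts = [make_post("1", {"a"}, user="spam"), make_post("2", {"a"}, user="ok")]
        out, removed = apply_blocklist(Corpus("x", posts), Blocklist(set(), {"spam"}))
        assert removed == 1
        assert out.posts[0].user_id == "ok"

    def test_empty_blocklist_identity(self):
        corpus = make_corpus([{"a"}, {"b"}])
        out, removed = apply_blocklist(corpus, Blocklist())
        assert removed == 0 and len(out) == 2

    def test_count_removed(self):
        sets = [{"x", "bad"}] * 4 + [{"x"}] * 6
        out, removed = apply_blocklist(make_corpus(sets), Blocklist({"bad"}, set()))
        assert removed == 4 and len(out) == 6


class TestDetectors:
    def test_identical_posts_flagged(self):
        tags = {"a", "b", "c", "d", "e", "f", "g", "h"}
        posts = [make_post(f"p{i}", tags, user="bot") for i in range(3)]
        flagged, counts = detect_automated_posts(
            Corpus("x", posts), jaccard_threshold=0.9, min_cluster=3
        )
        assert flagged == {"p0", "p1", "p2"}
        assert counts["graph"] == 3

    def test_distinct_posts_unflagged(self):
        posts = [make_post(f"p{i}", {f"t{i}"}) for i in range(10)]
        flagged, _ = detect_automated_posts(Corpus("x", posts))
        assert flagged == set()

    def test_empty_corpus(self):
        flagged, _ = detect_automated_posts(Corpus("x", []))
        assert flagged == set()

    def test_cluster_below_min_size_unflagged(self):
        tags = {"a", "b", "c", "d", "e", "f", "g", "h"}
        posts = [make_post(f"p{i}", tags) for i in range(2)]
        flagged, _ = detect_automated_posts(
            Corpus("x", posts), jaccard_threshold=0.9, min_cluster=3
        )
        assert flagged == set()

    def test_bad_params_rejected(self):
        with pytest.raises(ConfigError, match="jaccard_threshold"):
            detect_automated_posts(Corpus("x", []), jaccard_threshold=0.0)
        with pytest.raises(ConfigError, match="min_cluster"):
            detect_automated_posts(Corpus("x", []), min_cluster=1)

    def test_volume_anomaly_detector(self):
        posts = [make_post(f"h{i}", {f"t{i}", f"u{i}"}, user=f"u{i}") for i in range(30)]
        posts += [make_post(f"b{i}", {f"x{i}", f"y{i}"}, user="heavy") for i in range(40)]
        flagged, counts = detect_automated_posts(
            Corpus("x", posts), use_anomaly=True, rate_zscore=3.0
        )
        assert {p for p in flagged if p.startswith("b")} == {f"b{i}" for i in range(40)}
        assert counts["anomaly"] == 40

    def test_burst_detector(self):
        # one user posts 20 times within a minute plus 20 spread over a year
        burst = [
            make_post(f"b{i}", {f"t{i}"}, user="bursty",
                      ts=f"2019-06-01T12:00:{i:02d}Z")
            for i in range(20)
        ]
        spread = [
            make_post(f"s{i}", {f"s{i}"}, user="bursty",
                      ts=f"2019-{(i % 12) + 1:02d}-{(i % 27) + 1:02d}T01:00:00Z")
            for i in range(20)
        ]
        flagged, counts = detect_automated_posts(
            Corpus("x", burst + spread), use_timeseries=True, rate_window=3600.0
        )
        assert counts["timeseries"] == 40  # whole user flagged

    def test_synthetic_precision_recall(self):
        cfg = GeneratorConfig(
            n_areas=1, posts_per_area=2000, bot_fraction=0.1, bot_jitter=0.05,
            bot_template_size=10, ad_fraction=0.0, seed=17,
        )
        corpus = generate_corpus(cfg, 0)
        truth = {p.post_id for p in corpus if p.truth_label == "bot"}
        flagged, _ = detect_automated_posts(corpus)
        tp = len(flagged & truth)
        assert tp / len(flagged) >= 0.9
        assert tp / len(truth) >= 0.9


class TestClean:
    def test_clean_corpus_no_discards(self):
        corpus = make_corpus([{f"t{i}", "common"} for i in range(10)])
        cleaned, report = clean(corpus)
        assert report.discard_fraction == 0.0
        assert report.warnings == []
        assert len(cleaned) == 10

    def test_conservation(self):
        cfg = GeneratorConfig(n_areas=1, posts_per_area=500, bot_fraction=0.1, seed=3)
        corpus = generate_corpus(cfg, 0)
        _, report = clean(
            corpus, Blocklist(set(cfg.ad_tags), set()),
            SynonymMap.from_groups(cfg.synonym_groups),
        )
        assert report.n_retained + report.n_flagged_bot + report.n_flagged_blocklist \
            == report.n_input

    def test_discard_warning_fires_above_quarter(self):
        # 6 of 20 posts blocklisted -> 30% discard, warning expected
        sets = [{"bad", f"t{i}"} for i in range(6)] + [{f"t{i}"} for i in range(6, 20)]
        _, report = clean(make_corpus(sets), Blocklist({"bad"}, set()))
        assert report.discard_fraction == pytest.approx(0.3)
        assert report.warnings

    def test_discard_warning_silent_at_quarter(self):
        # exactly 25% discarded: the observed ceiling, no warning
        sets = [{"bad", f"t{i}"} for i in range(5)] + [{f"t{i}"} for i in range(5, 20)]
        _, report = clean(make_corpus(sets), Blocklist({"bad"}, set()))
        assert report.discard_fraction == pytest.approx(0.25)
        assert report.warnings == []

    def test_idempotent(self):
        cfg = GeneratorConfig(
            n_areas=1, posts_per_area=400, bot_fraction=0.1, ad_fraction=0.05, seed=8
        )
        corpus = generate_corpus(cfg, 0)
        bl = Blocklist(set(cfg.ad_tags), set())
        sm = SynonymMap.from_groups(cfg.synonym_groups)
        once, _ = clean(corpus, bl, sm)
        twice, report2 = clean(once, bl, sm)
        assert [p.hashtags for p in twice] == [p.hashtags for p in once]
        assert report2.discard_fraction == 0.0

    def test_synthetic_discard_fraction_matches_truth(self):
        cfg = GeneratorConfig(
            n_areas=1, posts_per_area=2000, bot_fraction=0.2, ad_fraction=0.1, seed=4
        )
        corpus = generate_corpus(cfg, 0)
        _, report = clean(
            corpus, Blocklist(set(cfg.ad_tags), set()),
            SynonymMap.from_groups(cfg.synonym_groups),
        )
        assert 0.25 <= report.discard_fraction <= 0.35
        if report.discard_fraction > 0.25:
            assert report.warnings

    def test_empty_corpus(self):
        cleaned, report = clean(Corpus("x", []))
        assert len(cleaned) == 0
        assert report.n_input == 0 and report.discard_fraction == 0.0
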