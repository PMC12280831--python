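"""Tests for guide scaling, word scores, top-word selection and ranking."""

import numpy as np
import pytest

from wellrec import (
    GuideStats,
    MissingStatsError,
    RecommenderConfig,
    SessionLibrary,
    SessionMeta,
    guide_scaler_A,
    guide_stats,
    rank_sessions,
    raw_word_scores,
    recommend,
    scale_word_scores,
    select_top_words,
    total_word_scores,
)
from conftest import make_history, make_library
from helpers import brute_force_recommend


class TestGuideScaler:
    STATS = GuideStats(mean_benefit={"g1": 0.3, "g2": 0.1, "g3": -0.1})

    def test_endpoints_of_the_interpolation(self):
        cfg = RecommenderConfig(guide_weight=1.0)
        assert guide_scaler_A(self.STATS, "g1", cfg) == pytest.approx(2.0)
        assert guide_scaler_A(self.STATS, "g3", cfg) == pytest.approx(1.0)
        assert guide_scaler_A(self.STATS, "g2", cfg) == pytest.approx(1.5)

    def test_zero_weight_disables_scaling(self):
        cfg = RecommenderConfig(guide_weight=0.0)
        for g in self.STATS.mean_benefit:
            assert guide_scaler_A(self.STATS, g, cfg) == 1.0

    def test_single_guide_degenerate_range(self):
        stats = GuideStats(mean_benefit={"g1": 0.7})
        assert guide_scaler_A(stats, "g1") == 1.0

    def test_unknown_guide(self):
        with pytest.raises(MissingStatsError):
            guide_scaler_A(self.STATS, "g9")

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0, 3.0])
    def test_bounded_and_monotone_in_guide_mean(self, w):
        rng = np.random.default_rng(1)
        cfg = RecommenderConfig(guide_weight=w)
        for _ in range(20):
            means = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=5))}
            stats = GuideStats(mean_benefit=means)
            values = {g: guide_scaler_A(stats, g, cfg) for g in means}
            assert all(1.0 <= a <= 1.0 + w + 1e-12 for a in values.values())
            order = sorted(means, key=means.get)
            scaled = [values[g] for g in order]
            assert all(a <= b + 1e-12 for a, b in zip(scaled, scaled[1:]))


class TestWordScores:
    def test_each_payload_word_receives_the_session_benefit(self):
        lib = make_library(4, seed=3)
        history = make_history(lib, [0.2], measure="osl")
        table = raw_word_scores(list(history), lib, "osl")
        meta = lib[history.records[0].session_id]
        for w in meta.mood_words:
            assert table.mood[w].raw == pytest.approx([0.2])
        for w in meta.intent_words:
            assert table.intent[w].raw == pytest.approx([0.2])
        assert len(table.mood) == 3 and len(table.intent) == 3

    def test_shared_word_accumulates_both_sessions(self):
        metas = [
            SessionMeta("a", "g1", ("calm", "happy", "tense"), ("rest", "focus", "sleep")),
            SessionMeta("b", "g1", ("calm", "gloomy", "bored"), ("rest", "energy", "clarity")),
        ]
        lib = SessionLibrary.from_metas(metas)
        history = make_history(lib, [0.1, -0.1], session_ids=["a", "b"])
        table = raw_word_scores(list(history), lib, "osl")
        assert table.mood["calm"].raw == pytest.approx([0.1, -0.1])
        table = total_word_scores(scale_word_scores(table, guide_stats(list(history), lib, "osl")))
        assert table.mood["calm"].total == pytest.approx(0.0)

    def test_scaling_is_elementwise_product(self):
        stats = GuideStats(mean_benefit={"g1": 0.0, "g2": 0.2})
        metas = [
            SessionMeta("a", "g2", ("calm", "happy", "tense"), ("rest", "focus", "sleep")),
        ]
        lib = SessionLibrary.from_metas(metas)
        history = make_history(lib, [0.2], session_ids=["a"])
        table = raw_word_scores(list(history), lib, "osl")
        scale_word_scores(table, stats, RecommenderConfig(guide_weight=1.0))
        assert table.mood["calm"].scaled == pytest.approx([0.4])  # A = 2 at the top guide
        scale_word_scores(table, stats, RecommenderConfig(guide_weight=0.0))
        assert table.mood["calm"].scaled == pytest.approx(table.mood["calm"].raw)


class TestTopWordsAndRanking:
    def test_top_by_total_with_lexicographic_ties(self):
        from wellrec.recommend import WordScores

        lib = make_library(6, seed=5)
        table = raw_word_scores([], lib, "osl")
        table.mood = {w: WordScores(total=t) for w, t in
                      {"a": 0.5, "b": 0.4, "c": 0.3, "d": 0.1}.items()}
        table.intent = {w: WordScores(total=t) for w, t in
                        {"x": 0.2, "y": 0.2, "z": 0.1, "w": 0.05}.items()}
        top_mood, top_intent = select_top_words(table, lib)
        assert top_mood == ("a", "b", "c")
        assert top_intent == ("x", "y", "z")  # x before y on the tie

    def test_shortfall_padded_from_library_vocab(self):
        from wellrec.recommend import WordScores

        lib = make_library(6, seed=5)
        table = raw_word_scores([], lib, "osl")
        table.mood = {"zz_observed": WordScores(total=0.4)}
        table.intent = {}
        top_mood, top_intent = select_top_words(table, lib)
        assert top_mood[0] == "zz_observed"
        assert top_mood[1:] == tuple(w for w in lib.vocab("mood") if w != "zz_observed")[:2]
        assert top_intent == lib.vocab("intent")[:3]

    def test_association_score_by_hand(self):
        from wellrec.recommend import WordScores, WordScoreTable

        metas = [
            SessionMeta("full", "g1", ("a", "b", "c"), ("x", "y", "z")),
            SessionMeta("none", "g1", ("d", "e", "f"), ("u", "v", "q")),
            SessionMeta("part", "g1", ("a", "d", "e"), ("x", "u", "v")),
        ]
        lib = SessionLibrary.from_metas(metas)
        table = WordScoreTable(
            mood={w: WordScores(total=t) for w, t in {"a": 0.5, "b": 0.4, "c": 0.3}.items()},
            intent={w: WordScores(total=t) for w, t in {"x": 0.2, "y": 0.2, "z": 0.1}.items()},
        )
        rec = rank_sessions(lib, ("a", "b", "c"), ("x", "y", "z"), table)
        scores = dict(rec.ranked_sessions)
        assert scores["full"] == pytest.approx(1.7)
        assert scores["none"] == 0.0
        assert scores["part"] == pytest.approx(0.7)
        assert rec.ranked_sessions[0][0] == "full"

    def test_negative_totals_cannot_boost_a_session(self):
        from wellrec.recommend import WordScores, WordScoreTable

        metas = [
            SessionMeta("neg", "g1", ("a", "b", "c"), ("x", "y", "z")),
            SessionMeta("alt", "g1", ("d", "e", "f"), ("u", "v", "q")),
        ]
        lib = SessionLibrary.from_metas(metas)
        table = WordScoreTable(
            mood={"a": WordScores(total=-0.5)}, intent={"x": WordScores(total=-0.2)}
        )
        rec = rank_sessions(lib, ("a", "b", "c"), ("x", "y", "z"), table)
        assert dict(rec.ranked_sessions)["neg"] == 0.0


class TestRecommendEndToEnd:
    def test_k_bounds(self):
        lib = make_library(5)
        history = make_history(lib, [0.1, 0.2])
        with pytest.raises(ValueError):
            recommend(history, lib, "osl", k=0)
        with pytest.raises(ValueError):
            recommend(history, lib, "osl", k=3)

    def test_single_session_base_case(self):
        lib = make_library(8, seed=11)
        history = make_history(lib, [0.3], measure="osl")
        rec = recommend(history, lib, "osl", k=1)
        meta = lib[history.records[0].session_id]
        assert set(rec.top_mood_words) == set(meta.mood_words)
        assert set(rec.top_intent_words) == set(meta.intent_words)
        assert rec.ranked_sessions[0][0] == min(
            [m.session_id for m in lib if dict(rec.ranked_sessions)[m.session_id]
             == rec.ranked_sessions[0][1]]
        )

    def test_benefit_scale_invariance(self):
        """Multiplying every benefit by c > 0 preserves selection and ranking."""
        lib = make_library(7, seed=2)
        benefits = [0.1, -0.05, 0.2, 0.15, -0.1]
        r1 = recommend(make_history(lib, benefits), lib, "osl", k=5)
        r2 = recommend(make_history(lib, [2.5 * b for b in benefits]), lib, "osl", k=5)
        assert r1.top_mood_words == r2.top_mood_words
        assert r1.top_intent_words == r2.top_intent_words
        assert [s for s, _ in r1.ranked_sessions] == [s for s, _ in r2.ranked_sessions]

    def test_guide_label_invariance_at_zero_weight(self):
        lib = make_library(6, n_guides=3, seed=9)
        permuted = SessionLibrary.from_metas(
            SessionMeta(m.session_id, {"g01": "g02", "g02": "g03", "g03": "g01"}[m.guide_id],
                        m.mood_words, m.intent_words)
            for m in lib
        )
        history = make_history(lib, [0.1, 0.3, -0.2, 0.05])
        cfg = RecommenderConfig(guide_weight=0.0)
        r1 = recommend(history, lib, "osl", cfg, k=4)
        r2 = recommend(history, permuted, "osl", cfg, k=4)
        assert r1.ranked_sessions == r2.ranked_sessions

    def test_one_guide_library_ignores_guide_weight(self):
        lib = make_library(6, n_guides=1, seed=4)
        history = make_history(lib, [0.1, 0.3, -0.2])
        r0 = recommend(history, lib, "osl", RecommenderConfig(guide_weight=0.0), k=3)
        r1 = recommend(history, lib, "osl", RecommenderConfig(guide_weight=1.0), k=3)
        assert r0.ranked_sessions == r1.ranked_sessions

    def test_storage_order_does_not_matter(self):
        lib = make_library(5, seed=6)
        history = make_history(lib, [0.1, 0.2, -0.1])
        from wellrec import UserHistory

        shuffled = UserHistory(
            user_id=history.user_id, records=tuple(reversed(history.records))
        )
        assert (
            recommend(history, lib, "osl", k=2).ranked_sessions
            == recommend(shuffled, lib, "osl", k=2).ranked_sessions
        )

    @pytest.mark.parametrize("measure", ["osl", "srs", "srm"])
    def test_matches_brute_force_on_small_problems(self, measure):
        rng = np.random.default_rng(0)
        for trial in range(10):
            lib = make_library(int(rng.integers(3, 9)), n_guides=3, seed=100 + trial)
            n = int(rng.integers(2, 7))
            benefits = list(rng.normal(0, 0.15, size=n))
            ids = [str(s) for s in rng.choice(lib.session_ids, size=n)]
            history = make_history(lib, benefits, measure=measure, session_ids=ids)
            w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            k = int(rng.integers(1, n + 1))
            rec = recommend(history, lib, measure, RecommenderConfig(guide_weight=w), k=k)
            bf_mood, bf_intent, _, _, bf_rank = brute_force_recommend(
                history, lib, measure, w, k
            )
            assert rec.top_mood_words == bf_mood
            assert rec.top_intent_words == bf_intent
            assert [s for s, _ in rec.ranked_sessions] == [s for s, _ in bf_rank]
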