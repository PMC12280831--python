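"""The word-score therapy recommender.

A noncollaborative user-item algorithm: it looks only at one user's own
pre/post deltas, never at other users.  From a training window of completed
sessions it derives, per payload word, a *raw score* R (the oriented benefit
of each training session whose payload contains the word), scales it by a
guide factor A (guides that were historically more efficacious for this
user up-weight their words), sums to a *total score* T per word, picks the
3 mood and 3 intent words with the greatest T, and finally ranks the entire
session library by the summed positive T of the top words each session
carries.  The top-3 ranked sessions are the algorithmically selected (AS)
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import MissingStatsError
from .measures import (
    MeasureSpec,
    SessionLibrary,
    SessionRecord,
    UserHistory,
    get_measure,
    oriented_benefit,
)


@dataclass(frozen=True)
class RecommenderConfig:
    """Tunable recommender parameters.

    The defaults reproduce the production setting: guide weight W = 1 and
    the two reserved scalers B and C passed through as 1.
    """

    guide_weight: float = 1.0
    scaler_b: float = 1.0
    scaler_c: float = 1.0
    n_top_mood: int = 3
    n_top_intent: int = 3
    n_recommendations: int = 3

    def __post_init__(self) -> None:
        if self.guide_weight < 0:
            raise ValueError("guide_weight must be >= 0")


DEFAULT_CONFIG = RecommenderConfig()


@dataclass(frozen=True)
class GuideStats:
    """Per-user guide efficacy: mean oriented benefit of each guide's sessions."""

    mean_benefit: dict[str, float]

    @property
    def g_min(self) -> float:
        return min(self.mean_benefit.values())

    @property
    def g_max(self) -> float:
        return max(self.mean_benefit.values())


def guide_stats(
    train: Sequence[SessionRecord],
    library: SessionLibrary,
    measure: MeasureSpec | str,
) -> GuideStats:
    """Mean oriented benefit per guide over the training records."""
    spec = get_measure(measure)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in train:
        guide = library[rec.session_id].guide_id
        sums[guide] = sums.get(guide, 0.0) + oriented_benefit(rec, spec)
        counts[guide] = counts.get(guide, 0) + 1
    return GuideStats(mean_benefit={g: sums[g] / counts[g] for g in sums})


def guide_scaler_A(
    stats: GuideStats, guide_id: str, config: RecommenderConfig = DEFAULT_CONFIG
) -> float:
    """Guide scaler A = 1 + W * (g_mean − g_min) / (g_max − g_min).

    Min-max interpolation over the user's own guides: the least efficacious
    guide maps to 1, the most efficacious to 1 + W.  Degenerate range (a
    single guide, or all guides tied) maps to 1, as does W = 0.
    """
    if guide_id not in stats.mean_benefit:
        raise MissingStatsError(f"no training sessions for guide {guide_id!r}")
    w = config.guide_weight
    lo, hi = stats.g_min, stats.g_max
    if w == 0 or hi == lo:
        return 1.0
    return 1.0 + w * (stats.mean_benefit[guide_id] - lo) / (hi - lo)


@dataclass
class WordScores:
    """Score lists for one word: raw R per training session, scaled S, total T."""

    raw: list[float] = field(default_factory=list)
    guide_ids: list[str] = field(default_factory=list)
    scaled: list[float] = field(default_factory=list)
    total: float = 0.0


@dataclass
class WordScoreTable:
    """Per-word score bookkeeping, kept separately for mood and intent words."""

    mood: dict[str, WordScores] = field(default_factory=dict)
    intent: dict[str, WordScores] = field(default_factory=dict)

    def by_class(self, word_class: str) -> dict[str, WordScores]:
        return self.mood if word_class == "mood" else self.intent

    def total_of(self, word_class: str, word: str) -> float:
        scores = self.by_class(word_class).get(word)
        return 0.0 if scores is None else scores.total


def raw_word_scores(
    train: Sequence[SessionRecord],
    library: SessionLibrary,
    measure: MeasureSpec | str,
) -> WordScoreTable:
    """Fill R: each payload word of each training session receives that
    session's oriented benefit as one raw-score entry."""
    spec = get_measure(measure)
    table = WordScoreTable()
    for rec in train:
        meta = library[rec.session_id]
        b = oriented_benefit(rec, spec)
        for word in meta.mood_words:
            scores = table.mood.setdefault(word, WordScores())
            scores.raw.append(b)
            scores.guide_ids.append(meta.guide_id)
        for word in meta.intent_words:
            scores = table.intent.setdefault(word, WordScores())
            scores.raw.append(b)
            scores.guide_ids.append(meta.guide_id)
    return table


def scale_word_scores(
    table: WordScoreTable,
    stats: GuideStats,
    config: RecommenderConfig = DEFAULT_CONFIG,
) -> WordScoreTable:
    """Fill S = R * A(guide) * B * C for every raw-score entry."""
    bc = config.scaler_b * config.scaler_c
    a_cache = {g: guide_scaler_A(stats, g, config) for g in stats.mean_benefit}
    for words in (table.mood, table.intent):
        for scores in words.values():
            scores.scaled = [
                r * a_cache[g] * bc for r, g in zip(scores.raw, scores.guide_ids)
            ]
    return table


def total_word_scores(table: WordScoreTable) -> WordScoreTable:
    """Fill T = sum of the scaled scores per word."""
    for words in (table.mood, table.intent):
        for scores in words.values():
            scores.total = sum(scores.scaled)
    return table


def select_top_words(
    table: WordScoreTable,
    library: SessionLibrary,
    config: RecommenderConfig = DEFAULT_CONFIG,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The mood and intent words with the greatest T.

    Ties break lexicographically.  If fewer words were observed than slots,
    the shortfall is filled lexicographically from the library's unobserved
    (T = 0) words of that class.
    """
    result = []
    for word_class, n_top in (("mood", config.n_top_mood), ("intent", config.n_top_intent)):
        observed = table.by_class(word_class)
        ranked = sorted(observed, key=lambda w: (-observed[w].total, w))
        chosen = ranked[:n_top]
        if len(chosen) < n_top:
            pool = [w for w in library.vocab(word_class) if w not in observed]
            chosen += pool[: n_top - len(chosen)]
        result.append(tuple(chosen))
    return result[0], result[1]


@dataclass(frozen=True)
class Recommendation:
    """Output of one recommender fit: top words, full ranking, AS sessions."""

    user_id: str
    measure: str
    k: int
    top_mood_words: tuple[str, ...]
    top_intent_words: tuple[str, ...]
    ranked_sessions: tuple[tuple[str, float], ...]  # (session_id, score), best first
    as_sessions: tuple[str, ...]


def rank_sessions(
    library: SessionLibrary,
    top_mood: Sequence[str],
    top_intent: Sequence[str],
    table: WordScoreTable,
    config: RecommenderConfig = DEFAULT_CONFIG,
    user_id: str = "",
    measure: str = "",
    k: int = 0,
) -> Recommendation:
    """Rank every library session by its association with the top-6 words.

    Association score of a session = sum of max(T(w), 0) over the payload
    words it shares with the top words (mood matched against top mood words,
    intent against top intent).  Negative-T words cannot boost a session.
    Ties break lexicographically on session_id.
    """
    if len(library) == 0:
        raise ValueError("cannot rank an empty session library")
    mood_weight = {w: max(table.total_of("mood", w), 0.0) for w in top_mood}
    intent_weight = {w: max(table.total_of("intent", w), 0.0) for w in top_intent}
    scored = []
    for meta in library:
        score = sum(mood_weight.get(w, 0.0) for w in meta.mood_words)
        score += sum(intent_weight.get(w, 0.0) for w in meta.intent_words)
        scored.append((meta.session_id, score))
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return Recommendation(
        user_id=user_id,
        measure=measure,
        k=k,
        top_mood_words=tuple(top_mood),
        top_intent_words=tuple(top_intent),
        ranked_sessions=tuple(scored),
        as_sessions=tuple(sid for sid, _ in scored[: config.n_recommendations]),
    )


def recommend(
    history: UserHistory,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    config: RecommenderConfig = DEFAULT_CONFIG,
    k: int = 1,
) -> Recommendation:
    """Fit the recommender on the first ``k`` records of one user's history."""
    if k < 1:
        raise ValueError("training size k must be >= 1")
    if k > len(history):
        raise ValueError(f"k={k} exceeds history length {len(history)}")
    spec = get_measure(measure)
    train = [r for r in history if r.order_index <= k]
    stats = guide_stats(train, library, spec)
    table = raw_word_scores(train, library, spec)
    table = scale_word_scores(table, stats, config)
    table = total_word_scores(table)
    top_mood, top_intent = select_top_words(table, library, config)
    return rank_sessions(
        library, top_mood, top_intent, table, config,
        user_id=history.user_id, measure=spec.name, k=k,
    )
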