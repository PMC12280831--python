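"""Independent brute-force re-implementation of the recommender.

Deliberately straight-line code with no shared machinery: used as the
oracle that the pipeline implementation is checked against on small
problems.
"""

from __future__ import annotations


def brute_force_recommend(history, library, measure, guide_weight, k,
                          scaler_b=1.0, scaler_c=1.0, n_rec=3):
    """Recompute top words, word totals and the session ranking from scratch.

    Returns (top_mood, top_intent, totals_mood, totals_intent, ranking).
    """
    direction = {"osl": -1.0, "srs": -1.0, "srm": +1.0}[measure]
    train = [r for r in history if r.order_index <= k]

    def benefit(rec):
        pre = getattr(rec, f"{measure}_pre")
        post = getattr(rec, f"{measure}_post")
        return direction * (post - pre)

    # guide means of oriented benefit
    guide_vals = {}
    for rec in train:
        g = library[rec.session_id].guide_id
        guide_vals.setdefault(g, []).append(benefit(rec))
    guide_mean = {g: sum(v) / len(v) for g, v in guide_vals.items()}
    lo, hi = min(guide_mean.values()), max(guide_mean.values())

    def scaler_a(g):
        if guide_weight == 0 or hi == lo:
            return 1.0
        return 1.0 + guide_weight * (guide_mean[g] - lo) / (hi - lo)

    totals_mood: dict[str, float] = {}
    totals_intent: dict[str, float] = {}
    for rec in train:
        meta = library[rec.session_id]
        s = benefit(rec) * scaler_a(meta.guide_id) * scaler_b * scaler_c
        for w in meta.mood_words:
            totals_mood[w] = totals_mood.get(w, 0.0) + s
        for w in meta.intent_words:
            totals_intent[w] = totals_intent.get(w, 0.0) + s

    def top3(totals, word_class):
        ranked = sorted(totals, key=lambda w: (-totals[w], w))[:3]
        if len(ranked) < 3:
            seen = set()
            for meta in library:
                words = meta.mood_words if word_class == "mood" else meta.intent_words
                seen.update(words)
            pool = sorted(w for w in seen if w not in totals)
            ranked += pool[: 3 - len(ranked)]
        return tuple(ranked)

    top_mood = top3(totals_mood, "mood")
    top_intent = top3(totals_intent, "intent")

    ranking = []
    for meta in library:
        score = 0.0
        for w in meta.mood_words:
            if w in top_mood:
                score += max(totals_mood.get(w, 0.0), 0.0)
        for w in meta.intent_words:
            if w in top_intent:
                score += max(totals_intent.get(w, 0.0), 0.0)
        ranking.append((meta.session_id, score))
    ranking.sort(key=lambda pair: (-pair[1], pair[0]))
    return top_mood, top_intent, totals_mood, totals_intent, ranking
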