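import numpy as np
import pytest

from wellrec import (
    MoodLexicon,
    SessionLibrary,
    SessionMeta,
    SessionRecord,
    UserHistory,
    default_lexicon,
)


@pytest.fixture(scope="session")
def lexicon() -> MoodLexicon:
    return default_lexicon()


def make_library(n_sessions=5, n_guides=2, seed=0) -> SessionLibrary:
    """Small random library drawn from the default vocabularies."""
    from wellrec import default_intent_vocab, default_payload_mood_vocab

    rng = np.random.default_rng(seed)
    mood_vocab = default_payload_mood_vocab()
    intent_vocab = default_intent_vocab()
    metas = []
    for i in range(n_sessions):
        metas.append(
            SessionMeta(
                session_id=f"s{i + 1:03d}",
                guide_id=f"g{rng.integers(n_guides) + 1:02d}",
                mood_words=tuple(str(w) for w in rng.choice(mood_vocab, 3, replace=False)),
                intent_words=tuple(str(w) for w in rng.choice(intent_vocab, 3, replace=False)),
            )
        )
    return SessionLibrary.from_metas(metas)


def make_history(
    library: SessionLibrary,
    benefits,
    user_id="u1",
    measure="osl",
    session_ids=None,
    seed=0,
) -> UserHistory:
    """History whose oriented benefits on ``measure`` equal ``benefits``.

    Other measures get neutral constant values; mood-board selections are
    fixed word pairs with zero net sentiment unless measure == 'srm'.
    """
    rng = np.random.default_rng(seed)
    ids = list(library.session_ids)
    records = []
    for i, b in enumerate(benefits):
        sid = session_ids[i] if session_ids else ids[i % len(ids)]
        osl_pre, osl_post = 0.5, 0.5
        srs_pre, srs_post = 5.0, 5.0
        words_pre = ("happy", "nervous")  # sigma = 0 -> SRM 0.5
        words_post = ("happy", "nervous")
        if measure == "osl":
            osl_pre, osl_post = 0.5, 0.5 - b  # decrease-beneficial
        elif measure == "srs":
            srs_pre, srs_post = 5.0, 5.0 - b
        elif measure == "srm":
            # realize an SRM delta of b via single-word selections where possible
            words_pre = ("happy", "nervous")
            target_post = 0.5 + b
            words_post = _words_for_value(target_post)
        records.append(
            SessionRecord.from_mood_words(
                user_id=user_id,
                session_id=sid,
                order_index=i + 1,
                osl_pre=osl_pre,
                osl_post=osl_post,
                srs_pre=srs_pre,
                srs_post=srs_post,
                mood_words_pre=words_pre,
                mood_words_post=words_post,
                lexicon=default_lexicon(),
            )
        )
    del rng
    return UserHistory(user_id=user_id, records=tuple(records))


def _words_for_value(target: float):
    """Two-word board selection whose SRM value is nearest ``target``.

    Two words span sigma in -4..4, i.e. SRM on a 9-level 1/8 grid.
    """
    from itertools import combinations

    lex = default_lexicon()
    best, best_err = None, np.inf
    for pair in combinations(lex.words, 2):
        value = (lex.score(pair[0]) + lex.score(pair[1]) + 4) / 8
        err = abs(value - target)
        if err < best_err:
            best, best_err = pair, err
    return best
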