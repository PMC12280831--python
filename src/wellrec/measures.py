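"""Well-being measures, session records, and delta/benefit computation.

Three well-being measures are tracked before and after every therapy session:

* **OSL** — objective stress level, a number in [0, 1] produced upstream by a
  facial-biomarker model (treated here as given input); lower is better.
* **SRS** — self-reported stress, a 0–10 slider value; lower is better.
* **SRM** — self-reported mood, a value in [0, 1] derived from the words a
  user taps on a mood board; higher is better.

The session-level quantity everything downstream consumes is the delta
``post − pre`` and its *oriented benefit*: the delta sign-adjusted so that a
larger value always means a more beneficial session, regardless of whether
the measure is "decrease is good" (stress) or "increase is good" (mood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompleteRecordError,
    MissingMeasureError,
    UnknownSessionError,
)
from .lexicon import MoodLexicon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureSpec:
    """One well-being measure: its range and which direction is beneficial."""

    name: str
    lo: float
    hi: float
    beneficial_direction: str  # "decrease" | "increase"

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("measure range must satisfy lo < hi")
        if self.beneficial_direction not in ("decrease", "increase"):
            raise ValueError("beneficial_direction must be 'decrease' or 'increase'")

    @property
    def span(self) -> float:
        return self.hi - self.lo


OSL = MeasureSpec("osl", 0.0, 1.0, "decrease")
SRS = MeasureSpec("srs", 0.0, 10.0, "decrease")
SRM = MeasureSpec("srm", 0.0, 1.0, "increase")

MEASURES: Mapping[str, MeasureSpec] = {"osl": OSL, "srs": SRS, "srm": SRM}


def get_measure(name: str | MeasureSpec) -> MeasureSpec:
    if isinstance(name, MeasureSpec):
        return name
    try:
        return MEASURES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown measure {name!r}; expected one of {list(MEASURES)}") from None


def score_mood_board(selected_words: Sequence[str], lexicon: MoodLexicon) -> float:
    """Convert a mood-board word selection into an SRM value in [0, 1].

    With ``k`` selected words and raw sentiment sum ``sigma`` (each word
    contributing its quadrant score in {-2, -1, +1, +2}), the value is
    ``(sigma + 2k) / (4k)`` — the affine map sending the most negative
    possible selection to 0, the most positive to 1, and a perfectly
    balanced selection to 0.5.
    """
    if not selected_words:
        raise MissingMeasureError("mood-board selection is empty")
    k = len(selected_words)
    sigma = sum(lexicon.score(w) for w in selected_words)
    return (sigma + 2 * k) / (4 * k)


def slider_face_value(quadrant: int) -> float:
    """SRS value of tapping face ``quadrant`` (1–4) on the stress slider.

    The four faces sit at the midpoints of the four quadrants of the 0–10
    slider: 1.25, 3.75, 6.25 and 8.75.
    """
    if quadrant not in (1, 2, 3, 4):
        raise ValueError(f"slider face quadrant must be 1..4, got {quadrant!r}")
    return 2.5 * (quadrant - 1) + 1.25


@dataclass(frozen=True)
class SessionMeta:
    """A therapy session: its guide and its 3 mood + 3 intent payload words."""

    session_id: str
    guide_id: str
    mood_words: tuple[str, str, str]
    intent_words: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.mood_words) != 3 or len(set(self.mood_words)) != 3:
            raise ValueError(f"session {self.session_id}: need 3 distinct mood words")
        if len(self.intent_words) != 3 or len(set(self.intent_words)) != 3:
            raise ValueError(f"session {self.session_id}: need 3 distinct intent words")

    @property
    def payload_words(self) -> tuple[str, ...]:
        return self.mood_words + self.intent_words


@dataclass(frozen=True)
class SessionLibrary:
    """The full catalogue of sessions available to every user."""

    sessions: Mapping[str, SessionMeta]

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions.values())

    def __contains__(self, session_id: str) -> bool:
        return session_id in self.sessions

    def __getitem__(self, session_id: str) -> SessionMeta:
        try:
            return self.sessions[session_id]
        except KeyError:
            raise UnknownSessionError(
                f"session {session_id!r} does not resolve in the library"
            ) from None

    @property
    def session_ids(self) -> tuple[str, ...]:
        return tuple(self.sessions)

    @property
    def guide_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.guide_id for m in self}))

    def vocab(self, word_class: str) -> tuple[str, ...]:
        """All distinct payload words of a class appearing in the library."""
        if word_class == "mood":
            words = {w for m in self for w in m.mood_words}
        elif word_class == "intent":
            words = {w for m in self for w in m.intent_words}
        else:
            raise ValueError("word_class must be 'mood' or 'intent'")
        return tuple(sorted(words))

    @classmethod
    def from_metas(cls, metas: Iterable[SessionMeta]) -> "SessionLibrary":
        return cls(sessions={m.session_id: m for m in metas})


@dataclass(frozen=True, slots=True)
class SessionRecord:
    """One completed session with all pre/post measurements.

    SRM values are derived from the stored mood-board word selections and
    cached on the record at construction time.
    """

    user_id: str
    session_id: str
    order_index: int
    osl_pre: float
    osl_post: float
    srs_pre: float
    srs_post: float
    mood_words_pre: tuple[str, ...]
    mood_words_post: tuple[str, ...]
    srm_pre: float
    srm_post: float

    @classmethod
    def from_mood_words(
        cls,
        user_id: str,
        session_id: str,
        order_index: int,
        osl_pre: float,
        osl_post: float,
        srs_pre: float,
        srs_post: float,
        mood_words_pre: Sequence[str],
        mood_words_post: Sequence[str],
        lexicon: MoodLexicon,
    ) -> "SessionRecord":
        return cls(
            user_id=user_id,
            session_id=session_id,
            order_index=int(order_index),
            osl_pre=float(osl_pre),
            osl_post=float(osl_post),
            srs_pre=float(srs_pre),
            srs_post=float(srs_post),
            mood_words_pre=tuple(mood_words_pre),
            mood_words_post=tuple(mood_words_post),
            srm_pre=score_mood_board(mood_words_pre, lexicon),
            srm_post=score_mood_board(mood_words_post, lexicon),
        )

    def pre(self, measure: MeasureSpec | str) -> float:
        value = getattr(self, f"{get_measure(measure).name}_pre", None)
        if value is None:
            raise IncompleteRecordError(
                f"record ({self.user_id}, {self.session_id}) missing pre value"
            )
        return value

    def post(self, measure: MeasureSpec | str) -> float:
        value = getattr(self, f"{get_measure(measure).name}_post", None)
        if value is None:
            raise IncompleteRecordError(
                f"record ({self.user_id}, {self.session_id}) missing post value"
            )
        return value


@dataclass(frozen=True)
class UserHistory:
    """One user's completed sessions in chronological order.

    ``order_index`` must be the gapless sequence 1..n; records are stored
    sorted by it, so downstream results never depend on input row order.
    """

    user_id: str
    records: tuple[SessionRecord, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.records, key=lambda r: r.order_index))
        object.__setattr__(self, "records", ordered)
        indices = [r.order_index for r in ordered]
        if indices != list(range(1, len(ordered) + 1)):
            raise ValueError(
                f"user {self.user_id}: order_index must be gapless 1..n, got {indices[:10]}..."
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


Cohort = Mapping[str, UserHistory]


def compute_delta(record: SessionRecord, measure: MeasureSpec | str) -> float:
    """Session delta ``post − pre`` on the measure's native scale."""
    spec = get_measure(measure)
    return record.post(spec) - record.pre(spec)


def orient_delta(delta: float, measure: MeasureSpec | str) -> float:
    """Sign-adjust a delta so that larger always means more beneficial."""
    spec = get_measure(measure)
    return -delta if spec.beneficial_direction == "decrease" else delta


def oriented_benefit(record: SessionRecord, measure: MeasureSpec | str) -> float:
    return orient_delta(compute_delta(record, measure), measure)


def zscore_within_user(values: Sequence[float]) -> np.ndarray:
    """Z-score one user's benefit values (sample sd, ddof=1).

    Zero variance (or fewer than two values) yields all-zeros with a
    warning rather than an error, so degenerate edge cases cannot abort a
    cohort-level run.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    if arr.size < 2:
        logger.warning("zscore_within_user: fewer than 2 values; returning zeros")
        return np.zeros_like(arr)
    sd = arr.std(ddof=1)
    if sd == 0.0:
        logger.warning("zscore_within_user: zero variance; returning zeros")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def deltas_frame(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-record table of native deltas and oriented benefits."""
    rows = []
    for history in cohort.values():
        for rec in history:
            row = {
                "user_id": rec.user_id,
                "session_id": rec.session_id,
                "order_index": rec.order_index,
            }
            for name, spec in MEASURES.items():
                d = compute_delta(rec, spec)
                row[f"delta_{name}"] = d
                row[f"benefit_{name}"] = orient_delta(d, spec)
            rows.append(row)
    return pd.DataFrame(rows)
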