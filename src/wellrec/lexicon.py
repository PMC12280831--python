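"""Mood-board lexicon and the payload vocabularies.

The mood board is a 2-axis (valence x arousal) grid of emotion words.  Each
word sits in one quadrant and carries a sentiment score:

* pleasant-intense  -> +2
* pleasant-mild     -> +1
* unpleasant-mild   -> -1
* unpleasant-intense-> -2

The bundled board has 32 words (8 per quadrant).  Therapy-session payloads
draw their three "mood words" from a slightly larger 36-word vocabulary (the
board words plus four neutral additions) and their three "intent words" from
a separate 24-word vocabulary.  All vocabularies can be overridden from CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import LexiconError

QUADRANT_SCORES: Mapping[str, int] = {
    "pleasant-intense": 2,
    "pleasant-mild": 1,
    "unpleasant-mild": -1,
    "unpleasant-intense": -2,
}

_BOARD_WORDS: Mapping[str, tuple[str, ...]] = {
    "pleasant-intense": (
        "happy", "delighted", "excited", "joyful",
        "thrilled", "elated", "inspired", "energized",
    ),
    "pleasant-mild": (
        "relaxed", "content", "calm", "peaceful",
        "serene", "comfortable", "grateful", "hopeful",
    ),
    "unpleasant-mild": (
        "depressed", "gloomy", "bored", "tired",
        "lonely", "sad", "weary", "discouraged",
    ),
    "unpleasant-intense": (
        "nervous", "tense", "anxious", "angry",
        "overwhelmed", "panicked", "frustrated", "irritated",
    ),
}

# Payload mood vocabulary = the 32 board words + 4 extra words that sessions
# may be tagged with but that never appear on the user-facing board.
_EXTRA_PAYLOAD_MOOD_WORDS: tuple[str, ...] = (
    "grounded", "balanced", "curious", "mindful",
)

_INTENT_WORDS: tuple[str, ...] = (
    "rest", "sleep", "focus", "confidence", "resilience", "gratitude",
    "compassion", "acceptance", "clarity", "energy", "courage", "patience",
    "forgiveness", "connection", "creativity", "motivation", "presence",
    "awareness", "breathing", "healing", "kindness", "purpose", "renewal",
    "stillness",
)


@dataclass(frozen=True)
class MoodLexicon:
    """Maps each board word to its quadrant (and hence its sentiment score)."""

    quadrant_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for word, quadrant in self.quadrant_of.items():
            if quadrant not in QUADRANT_SCORES:
                raise ValueError(f"unknown quadrant {quadrant!r} for word {word!r}")

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(sorted(self.quadrant_of))

    def __contains__(self, word: str) -> bool:
        return word in self.quadrant_of

    def __len__(self) -> int:
        return len(self.quadrant_of)

    def score(self, word: str) -> int:
        """Sentiment score in {-2, -1, +1, +2} of a board word."""
        try:
            return QUADRANT_SCORES[self.quadrant_of[word]]
        except KeyError:
            raise LexiconError(f"word {word!r} is not in the mood lexicon") from None

    @classmethod
    def from_words(cls, items: Iterable[tuple[str, str]]) -> "MoodLexicon":
        return cls(quadrant_of=dict(items))

    @classmethod
    def from_csv(cls, path) -> "MoodLexicon":
        """Read a ``word,quadrant`` CSV (header required)."""
        mapping: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["word"].strip()] = row["quadrant"].strip()
        return cls(quadrant_of=mapping)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["word", "quadrant"])
            for word in self.words:
                writer.writerow([word, self.quadrant_of[word]])


def default_lexicon() -> MoodLexicon:
    """The bundled 32-word board lexicon (8 words per quadrant)."""
    mapping = {
        word: quadrant
        for quadrant, words in _BOARD_WORDS.items()
        for word in words
    }
    return MoodLexicon(quadrant_of=mapping)


def default_payload_mood_vocab() -> tuple[str, ...]:
    """The 36-word vocabulary that session mood payloads draw from."""
    board = [w for words in _BOARD_WORDS.values() for w in words]
    return tuple(sorted(board + list(_EXTRA_PAYLOAD_MOOD_WORDS)))


def default_intent_vocab() -> tuple[str, ...]:
    """The 24-word vocabulary that session intent payloads draw from."""
    return tuple(sorted(_INTENT_WORDS))
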