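"""Exception types shared across the package."""


class WellrecError(Exception):
    """Base class for package-specific errors."""


class LexiconError(WellrecError, KeyError):
    """A mood word is not present in the active lexicon."""


class MissingMeasureError(WellrecError, ValueError):
    """A required pre/post measurement is absent (e.g. empty mood-board selection)."""


class IncompleteRecordError(WellrecError, ValueError):
    """A session record is missing a pre or post value for the requested measure."""


class UnknownSessionError(WellrecError, KeyError):
    """A session id does not resolve in the session library."""


class MissingStatsError(WellrecError, KeyError):
    """Guide statistics were requested for a guide absent from the training data."""


class ValidationError(WellrecError, ValueError):
    """An input file violates a hard constraint (range, duplicate, unresolved id)."""
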