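"""Exception types shared across the pipeline."""


class TrackermineError(Exception):
    """Base class for all package errors."""


class CsvFormatError(TrackermineError):
    """A CSV input is missing required columns or is otherwise malformed."""


class RowParseError(TrackermineError):
    """A single CSV row could not be parsed; message carries the line number."""


class CohortError(TrackermineError):
    """Participant bookkeeping violated (duplicate or unmatched ids)."""


class SpecError(TrackermineError):
    """A simulation spec is internally inconsistent (e.g. min rate > max rate)."""


class OutOfRangeError(TrackermineError):
    """A usage count exceeds the top bound of its discretization table."""


class ConsistencyError(TrackermineError):
    """An internal invariant failed (signals an upstream bug, not bad input)."""
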