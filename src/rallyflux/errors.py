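"""Exception hierarchy for rallyflux.

All errors derive from :class:`RallyfluxError` so callers can catch the
package's failures with a single except clause; each also subclasses
``ValueError`` because every one of them signals a bad input or a bad
combination of inputs.
"""


class RallyfluxError(ValueError):
    """Base class for all rallyflux errors."""


class InputError(RallyfluxError):
    """Malformed input data (file contents, outcome values, indices)."""


class ParseError(InputError):
    """A scoreline or other textual input could not be parsed."""


class InsufficientDataError(RallyfluxError):
    """A series is too short for the requested window."""


class DegenerateInputError(RallyfluxError):
    """A statistic is undefined on this input (e.g. constant series)."""


class UsageError(RallyfluxError):
    """An operation was called with arguments outside its contract."""
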