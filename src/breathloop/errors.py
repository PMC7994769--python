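"""Exception hierarchy for breathloop."""


class BreathloopError(Exception):
    """Base class for all breathloop errors."""


class ConfigurationError(BreathloopError, ValueError):
    """A configuration object or config file violates its invariants."""


class StreamOrderError(BreathloopError, ValueError):
    """Samples or events were pushed out of time order."""


class LogParseError(BreathloopError, ValueError):
    """A session log file is malformed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class LogValidationError(BreathloopError, ValueError):
    """A parsed session log violates a structural invariant (e.g. tick spacing)."""


class DesignError(BreathloopError, ValueError):
    """An analysis design requirement is not met (missing condition, degenerate fit)."""


class SummaryError(BreathloopError, ValueError):
    """A session record cannot be summarized (no defined rate estimates)."""
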