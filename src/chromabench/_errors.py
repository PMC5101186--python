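"""Exception hierarchy shared across the pipeline stages."""


class ChromabenchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChromabenchError):
    """A file violated its format contract.

    Carries the offending line number when known (1-based, ``None`` when the
    problem is not attributable to a single line).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(ChromabenchError):
    """A configuration value is out of contract (bad proportions, negative noise, ...)."""


class DesignError(ChromabenchError):
    """Sample/replicate design is inconsistent with the requested analysis."""


class AnalysisError(ChromabenchError):
    """An analysis precondition failed on otherwise valid inputs (e.g. zero total intensity)."""
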