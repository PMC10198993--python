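"""Exception types shared across the pipeline stages."""


class MirfishError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MirfishError):
    """Invalid configuration or generator specification."""


class ParseError(MirfishError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateFitError(MirfishError):
    """Degree distribution has too few distinct degrees for a log-log fit."""


class StageError(MirfishError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
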