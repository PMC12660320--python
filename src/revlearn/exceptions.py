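"""Exception hierarchy shared across the package.

All errors raised by revlearn derive from :class:`RevlearnError` so callers
can catch package failures with a single except clause while still being able
to discriminate configuration, parameter, data-integrity and schema problems.
"""


class RevlearnError(Exception):
    """Base class for all revlearn errors."""


class ConfigError(RevlearnError):
    """Invalid task / run configuration (names the offending field)."""


class ParameterError(RevlearnError):
    """Model or agent parameter outside its legal range."""


class DataError(RevlearnError):
    """Trial data violate an integrity constraint."""


class SchemaError(RevlearnError):
    """A delimited file is missing a required column or is malformed."""


class PipelineError(RevlearnError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
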