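"""Exception types shared across the package."""


class KerastateError(Exception):
    """Base class for all package errors."""


class ConfigError(KerastateError):
    """A configuration value is invalid; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DimensionError(KerastateError):
    """Array/mask dimensions do not agree."""


class PipelineError(KerastateError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
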