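"""Exception hierarchy for the pipeline."""


class RiboprofError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RiboprofError):
    """Invalid configuration or parameter values."""


class LibraryMismatchError(RiboprofError):
    """Reads from the wrong library type were passed to an operation."""


class StageError(RiboprofError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
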