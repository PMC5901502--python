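"""Exception hierarchy shared across the pipeline."""


class TranspolyError(Exception):
    """Base class for all pipeline errors."""


class InputError(TranspolyError):
    """An input file is unusable (missing columns, no samples, ...)."""


class ParseError(TranspolyError):
    """A record could not be parsed; the message names the offending line."""


class ValidationError(TranspolyError):
    """A parsed record violates a domain invariant; the message names it."""


class ConfigError(TranspolyError):
    """A configuration value is out of range or inconsistent."""


class FeatureError(TranspolyError):
    """A per-gene covariate could not be computed (e.g. exon past contig end)."""


class StageError(TranspolyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
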