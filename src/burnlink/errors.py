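"""Exception hierarchy shared across the package."""


class BurnlinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BurnlinkError, ValueError):
    """Item or latent-distribution parameters violate their invariants."""


class SchemaError(BurnlinkError, ValueError):
    """A response matrix, parameter file or config does not match its schema."""


class NoInformationError(BurnlinkError):
    """A respondent or pattern carries no observed responses to score."""


class LinkingUndefinedError(BurnlinkError):
    """Equipercentile linking is undefined (e.g. a degenerate score distribution)."""


class IncompatibleCrosswalkError(BurnlinkError):
    """Two crosswalks do not share an anchor metric and cannot be compared."""


class PipelineError(BurnlinkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
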