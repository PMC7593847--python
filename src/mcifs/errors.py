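"""Exception hierarchy shared across the package."""


class McifsError(Exception):
    """Base class for all package errors."""


class ValidationError(McifsError, ValueError):
    """An object violates one of its invariants."""


class ParseError(McifsError, ValueError):
    """A text input could not be parsed; message carries the line number."""


class ConfigError(McifsError, ValueError):
    """A configuration object is inconsistent with the data it is applied to."""


class PipelineError(McifsError, RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""
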