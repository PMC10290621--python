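"""Exception hierarchy shared across the pipeline stages."""


class CanprioError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(CanprioError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(CanprioError, ValueError):
    """A malformed input file; the message carries row/column or line context."""


class PipelineError(CanprioError, RuntimeError):
    """A stage of the end-to-end pipeline failed; the message names the stage."""
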