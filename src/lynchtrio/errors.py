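"""Exception types shared across the pipeline."""


class LynchtrioError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LynchtrioError):
    """Invalid simulation or analysis configuration."""


class ParseError(LynchtrioError):
    """Malformed input file."""


class DataIntegrityError(LynchtrioError):
    """Input contradicts itself or the reference sequence."""
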