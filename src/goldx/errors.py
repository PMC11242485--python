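"""Exception hierarchy for goldx."""


class GoldXError(Exception):
    """Base class for all goldx errors."""


class FormatError(GoldXError):
    """A file could not be read or is not in the expected format."""


class ParameterError(GoldXError):
    """A user-supplied parameter is out of range or inconsistent."""


class ConfigurationError(GoldXError):
    """A run cannot proceed with the resolved configuration."""
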