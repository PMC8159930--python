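"""Exception hierarchy shared across the package."""


class FlowContrastError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FlowContrastError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A cell or token could not be parsed; the message names its location."""


class ParameterError(FlowContrastError, ValueError):
    """A parameter value violates its documented constraints."""


class GeneNotFoundError(FlowContrastError, KeyError):
    """A requested gene symbol is absent from the relevant container."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return Exception.__str__(self)


class DisconnectedSourcesError(FlowContrastError):
    """No selected source gene survives filtering into the context network."""
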