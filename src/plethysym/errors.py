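"""Exception hierarchy shared across the pipeline."""


class PlethysymError(Exception):
    """Base class for all package errors."""


class ParameterError(PlethysymError, ValueError):
    """A function argument is outside its admissible range."""


class ValidationError(PlethysymError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(PlethysymError, ValueError):
    """A file does not conform to the expected on-disk layout."""
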