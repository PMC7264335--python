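"""Exception hierarchy for fluorequant.

All package-specific failures derive from :class:`FluoreQuantError` so callers
can catch one base class at pipeline level while tests assert on the precise
subclass.
"""


class FluoreQuantError(Exception):
    """Base class for all fluorequant errors."""


class ConfigurationError(FluoreQuantError):
    """A run configuration, role map, or rule is missing or inconsistent."""


class ValidationError(FluoreQuantError):
    """Tabular input (plate map, stack list) violates its contract."""


class FormatError(FluoreQuantError):
    """A file on disk is not in the expected format."""


class ParameterError(FluoreQuantError):
    """A numeric parameter is outside its legal range."""


class DensityError(FluoreQuantError):
    """Synthetic nuclei could not be placed without overlap at the
    requested density within the bounded number of attempts."""


class DegenerateInputError(FluoreQuantError):
    """An image is degenerate for the requested operation
    (e.g. constant image passed to an automatic threshold)."""


class DegenerateFieldError(FluoreQuantError):
    """A field of view leaves no pixels available for background estimation."""


class InsufficientControlError(FluoreQuantError):
    """Too few control values to estimate a control-null threshold."""
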