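"""Exception hierarchy shared across the toolkit."""


class BreastAsymError(Exception):
    """Base class for all toolkit errors."""


class ContractError(BreastAsymError, ValueError):
    """A caller violated an operation's precondition."""


class FormatError(BreastAsymError, ValueError):
    """An external file does not conform to its declared format."""


class ValidationError(BreastAsymError, ValueError):
    """Parsed data fails a plausibility or consistency check."""


class DegenerateInputError(BreastAsymError, ValueError):
    """Input is syntactically valid but carries no usable signal
    (e.g. a constant image handed to a thresholder)."""


class SegmentationFailure(BreastAsymError, RuntimeError):
    """The segmentation pipeline could not produce a usable mask/ROI."""
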