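"""Exception hierarchy shared by all pipeline stages."""


class ErpDecodeError(Exception):
    """Base class for all package errors."""


class ValidationError(ErpDecodeError):
    """Input values violate a documented precondition (e.g. a rating outside 1-9)."""


class FormatError(ErpDecodeError):
    """An on-disk container is missing required metadata or is internally inconsistent."""


class ShapeError(ErpDecodeError):
    """Array dimensions disagree with the accompanying metadata."""


class ConfigurationError(ErpDecodeError):
    """A configuration value is out of range or arithmetically impossible."""


class ParticipantExcluded(ErpDecodeError):
    """A participant/dimension lacks the rating variability required for analysis."""


class NumericalError(ErpDecodeError):
    """A numerical solve failed (singular system, non-convergence)."""
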