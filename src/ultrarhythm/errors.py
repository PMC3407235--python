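"""Exception types raised across the package."""


class UltrarhythmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(UltrarhythmError):
    """Input data violate a structural invariant (negative counts, bad grid...)."""


class FormatError(UltrarhythmError):
    """An on-disk file does not parse as the expected dialect."""


class InvalidPhotoperiodError(ValidationError):
    """Light hours outside the open interval (0, 24)."""


class ShortfallError(UltrarhythmError):
    """Not enough data to build the requested equalized series."""

    def __init__(self, available: int, required: int, what: str = "bins"):
        self.available = available
        self.required = required
        super().__init__(
            f"insufficient data: {available} {what} available, {required} required"
        )


class DegenerateSeriesError(UltrarhythmError):
    """Series has zero variance; no rhythm is definable."""


class UndefinedAlphaError(UltrarhythmError):
    """Activity-duration estimate undefined (flat or empty daily profile)."""


class SingularDesignError(UltrarhythmError):
    """Regression design matrix is rank deficient."""
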