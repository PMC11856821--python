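"""Exception hierarchy shared across the package."""


class SizedoseError(Exception):
    """Base class for all package errors."""


class ValidationError(SizedoseError, ValueError):
    """A record field violates a physical or logical constraint."""

    def __init__(self, field: str, message: str, exam_id: str | None = None):
        self.field = field
        self.exam_id = exam_id
        prefix = f"[{exam_id}] " if exam_id else ""
        super().__init__(f"{prefix}{field}: {message}")


class SchemaError(SizedoseError):
    """Input file does not match the documented cohort schema."""


class ConfigurationError(SizedoseError):
    """Invalid or incomplete configuration (unknown region, bad model...)."""


class RangeError(SizedoseError, ValueError):
    """Effective diameter outside the conversion model's validity range
    with clamping disabled."""


class InsufficientDataError(SizedoseError):
    """Too few observations for the requested statistical procedure."""


class CalibrationError(SizedoseError):
    """Monte-Carlo calibration could not reach the requested target."""
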