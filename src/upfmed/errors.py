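"""Exception types shared across the package."""


class UpfmedError(Exception):
    """Base class for package errors."""


class ClassificationError(UpfmedError):
    """A food code could not be assigned a NOVA group (e.g. dangling ingredient)."""


class UndefinedShareError(UpfmedError):
    """Energy share requested for a diary with zero total energy."""


class MissingDataError(UpfmedError):
    """A required field is absent; components are never silently scored zero."""


class CalibrationError(UpfmedError):
    """Generator calibration failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(UpfmedError):
    """A CSV table violates its declared schema."""
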