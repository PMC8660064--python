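"""Exception hierarchy shared by all sedem stages."""

from __future__ import annotations

from collections.abc import Sequence


class SedemError(Exception):
    """Base class for all errors raised by this package."""


class InvalidMeasurementError(SedemError):
    """A raw measurement is physically impossible (non-positive mass, Da > Dc, ...)."""


class InsufficientDataError(SedemError):
    """An aggregate was requested from too few observations."""


class InputValidationError(SedemError):
    """A record violates one of its declared invariants."""


class MissingFieldError(SedemError):
    """A required input field is absent; carries the affected parameter ids."""

    def __init__(self, message: str, parameters: Sequence[str] = ()):
        super().__init__(message)
        self.parameters = tuple(parameters)


class RegistryError(SedemError):
    """Unknown parameter id or malformed parameter registry."""


class ParseError(SedemError):
    """A CSV/JSON input could not be parsed; message names the offending cell."""


class ConfigError(SedemError):
    """Pipeline configuration is invalid (unknown key, bad value)."""
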