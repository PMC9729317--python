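"""Exception hierarchy used across plrkit."""


class PlrKitError(Exception):
    """Base class for all plrkit errors."""


class GridError(PlrKitError, ValueError):
    """Invalid wavelength or time grid (non-increasing, out of range)."""


class UnitsError(PlrKitError, ValueError):
    """Operation applied to a spectrum with the wrong units tag."""


class DomainError(PlrKitError, ValueError):
    """Argument outside its physical domain (e.g. non-positive diameter)."""


class SettingsError(PlrKitError, ValueError):
    """Malformed device settings (length, range, integrality)."""


class SwitchingRateError(PlrKitError, ValueError):
    """Video-file frames spaced closer than the device switching floor."""


class InsufficientDataError(PlrKitError, ValueError):
    """Not enough samples/levels for the requested computation."""


class FitError(PlrKitError, RuntimeError):
    """Curve fitting failed to converge or is ill-posed."""

    def __init__(self, message: str, led_index: int | None = None):
        super().__init__(message)
        self.led_index = led_index


class AllMaskedError(PlrKitError, ValueError):
    """Every sample was masked; downstream interpolation impossible."""


class EmptyInputError(PlrKitError, ValueError):
    """An operation received no data."""
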