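"""Exception and warning types shared across the package."""


class VitrophenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VitrophenError, ValueError):
    """A run configuration value is invalid or inconsistent with the image."""


class DimensionMismatchError(VitrophenError, ValueError):
    """Two rasters that must share a shape do not."""


class UndefinedTraitError(VitrophenError, ValueError):
    """A trait is undefined for this input (e.g. empty mask, no qualifying pixels).

    Carries ``n_qualifying`` when raised by the greenness computation so that
    callers can report how many pixels survived the chromatic filter.
    """

    def __init__(self, message: str, n_qualifying: int | None = None):
        super().__init__(message)
        self.n_qualifying = n_qualifying


class EmptyMaskWarning(UserWarning):
    """Segmentation produced an empty foreground mask; the run continues."""
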