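"""Exception hierarchy shared across the package.

Exit-code convention used by the CLI: 0 success, 2 input error
(:class:`InputError` and subclasses, missing files), 3 numerical or
degenerate-data error (:class:`DegenerateDataError`).
"""


class WtviError(Exception):
    """Base class for all package errors."""


class InputError(WtviError):
    """Malformed or inconsistent user input (bad file, bad config)."""


class BandCountMismatchError(InputError):
    """Raster band count does not match the supplied band map."""


class BandLookupError(InputError, KeyError):
    """A required center wavelength is not present in the band map."""


class UnreadableRasterError(InputError):
    """File exists but cannot be parsed as a supported raster container."""


class RoiError(InputError):
    """ROI outside image bounds, empty, or degenerate."""


class DegenerateDataError(WtviError):
    """Data that makes the requested computation ill-posed
    (zero-variance feature, all pixels invalid, too few samples)."""
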