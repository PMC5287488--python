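"""Exception types shared across the pipeline."""


class WristpaError(Exception):
    """Base class for all package errors."""


class FormatError(WristpaError):
    """A file does not conform to the expected on-disk layout."""


class DataError(WristpaError):
    """File parsed, but the data violate a hard invariant (e.g. time order)."""


class UncalibratableError(WristpaError):
    """Too few stationary windows, or insufficient orientation range, to fit
    a calibration model; the caller should borrow coefficients instead."""
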