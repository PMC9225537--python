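"""Exception hierarchy for melamet."""


class MelametError(Exception):
    """Base class for all melamet errors."""


class GridError(MelametError):
    """Two spectral objects do not share a wavelength grid."""


class RangeError(MelametError):
    """A target wavelength range falls outside the source range."""


class FormatError(MelametError):
    """A CSV file does not follow the spectra dialect."""


class SpectrumValidationError(MelametError):
    """Spectral values violate a physical constraint (e.g. negativity)."""


class DegeneracyError(MelametError):
    """The sensitivity set is (near-)linearly dependent."""


class ConstraintViolationError(MelametError):
    """A synthesized spectrum violates the device output bounds.

    Carries per-wavelength diagnostics in ``violations``: a list of
    ``(wavelength_nm, value, bound)`` tuples.
    """

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = violations or []


class CapacityError(MelametError):
    """A requested ipRGC modulation exceeds the feasible width.

    ``achievable`` holds the maximum feasible width in percent.
    """

    def __init__(self, message, achievable):
        super().__init__(message)
        self.achievable = achievable


class UndefinedChromaticityError(MelametError):
    """Chromaticity of an all-zero tristimulus vector is undefined."""
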