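"""Exception hierarchy for the fodspec package.

All errors raised by fodspec inherit from :class:`FodsError`, so callers
can catch the package's failures with a single except clause while still
discriminating the specific cause.
"""


class FodsError(Exception):
    """Base class for every error raised by fodspec."""


class SpectrumFormatError(FodsError, ValueError):
    """A spectrum file or table is malformed (bad columns, non-numeric
    cells, duplicate wavelengths). The message names the offending row."""


class GridError(FodsError, ValueError):
    """The wavelength grid violates the uniform-spacing contract, or a
    requested wavelength does not lie on the grid."""


class ParameterError(FodsError, ValueError):
    """An operation was called with invalid parameters (even smoothing
    window, too few spectra, empty level list, ...)."""


class DomainError(FodsError, ValueError):
    """A physically meaningless input (negative concentration, zero slope,
    non-positive mass, purity outside (0, 1])."""


class NoCrossingError(FodsError, RuntimeError):
    """No wavelength in the search window shows a consistent derivative
    sign change at every tested concentration."""


class DegenerateDesignError(FodsError, ValueError):
    """Calibration design is degenerate (all concentrations identical)."""


class InputError(FodsError, ValueError):
    """Invalid tabular input (e.g. duplicate batch/source rows)."""
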