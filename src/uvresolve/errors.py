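"""Exception hierarchy for uvresolve.

All errors derive from :class:`UvResolveError` so callers can catch the
package's failures with a single except clause; the finer-grained classes
distinguish file-format problems from numerical/degeneracy problems.
"""


class UvResolveError(Exception):
    """Base class for all uvresolve errors."""


class SpectrumFormatError(UvResolveError):
    """A spectrum file violates the expected CSV dialect or invariants."""


class RangeError(UvResolveError):
    """A wavelength or grid lies outside the span of the data (no extrapolation)."""


class DegenerateDivisorError(UvResolveError):
    """A divisor absorbance is at or below the safe floor."""


class DegenerateSpectraError(UvResolveError):
    """Two spectra are identical within tolerance where a crossing was requested."""


class IsoPointNotFoundError(UvResolveError):
    """No isoabsorptive crossing exists inside the search window."""


class MaskedWavelengthError(UvResolveError):
    """A read-off wavelength falls in a masked (unreliable) region of a ratio spectrum."""


class StabilityError(UvResolveError):
    """Deconvolution settings would amplify the Fourier domain past overflow."""


class DataError(UvResolveError):
    """A descriptor table is missing a required solvent/analyte entry."""
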