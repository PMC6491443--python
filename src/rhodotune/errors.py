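"""Exception hierarchy.

Everything raised on bad scientific input derives from :class:`RhodotuneError`
so callers can catch one base class; subclasses also derive from the matching
builtin (``ValueError``/``KeyError``/``RuntimeError``) for idiomatic handling.
"""


class RhodotuneError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RhodotuneError, ValueError):
    """Input outside the physical domain (e.g. non-positive wavelength)."""


class ConsistencyError(RhodotuneError, ValueError):
    """Mismatched labels, keys or grids between objects being combined."""


class FormatError(RhodotuneError, ValueError):
    """Malformed structure or table input."""


class MissingAtomError(FormatError):
    """A required chromophore atom is absent; ``.atom`` names it."""

    def __init__(self, atom: str):
        self.atom = atom
        super().__init__(f"required chromophore atom {atom!r} not found")


class DegenerateGeometryError(RhodotuneError, ValueError):
    """Geometry does not define the requested quantity (collinear atoms)."""


class SingularityError(RhodotuneError, ValueError):
    """Point charges too close for a meaningful Coulomb energy."""


class LookupError_(RhodotuneError, KeyError):
    """Unknown residue or key."""


class ConfigurationError(RhodotuneError, ValueError):
    """Missing or inconsistent configuration (parameters, mutated sites)."""


class EstimationError(RhodotuneError, RuntimeError):
    """An estimator could not produce a value (e.g. no bleach band)."""


class FitFailureError(RhodotuneError, RuntimeError):
    """A nonlinear fit did not converge; carries the residual trace."""

    def __init__(self, message: str, residual_trace=None):
        self.residual_trace = residual_trace
        super().__init__(message)


class GenerationError(RhodotuneError, ValueError):
    """A synthetic fixture cannot be built from the requested parameters."""


class DataError(RhodotuneError, ValueError):
    """Not enough data points for the requested analysis."""
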