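"""Exception and warning types shared across the package."""


class CardiomapError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CardiomapError, ValueError):
    """An argument is outside its mathematical domain (e.g. rho > 1)."""


class CoordinateError(CardiomapError, ValueError):
    """A Cartesian point is not on the modelled ventricular surface."""


class ValidationError(CardiomapError, ValueError):
    """An input table or configuration violates its schema or invariants."""


class FitError(CardiomapError, RuntimeError):
    """A regression/fit cannot be computed from the data supplied."""


class ZoneError(CardiomapError, ValueError):
    """A zone polygon is degenerate or inconsistent with the location set."""


class DegenerateScaleWarning(UserWarning):
    """All input values identical: the 0-100 display rescale is degenerate."""
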