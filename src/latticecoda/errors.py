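"""Exception hierarchy shared across the package."""


class LatticeCodaError(Exception):
    """Base class for all package-specific errors."""


class InvalidRangeError(LatticeCodaError, ValueError):
    """Grid bounds are inconsistent (hi < lo) or dimension < 2."""


class ZeroTotalError(LatticeCodaError, ValueError):
    """A vector with zero total cannot be closed or reduced to a ray."""


class LogDomainError(LatticeCodaError, ValueError):
    """A log-ratio transform received a non-positive part.

    Zeros must be handled first; see :mod:`latticecoda.zeros`.
    """


class EmptyInputError(LatticeCodaError, ValueError):
    """An operation received an empty grid or matrix."""


class InsufficientDataError(LatticeCodaError, ValueError):
    """A variance-based statistic needs at least two observations."""


class TwoPartCompositionError(LatticeCodaError, ValueError):
    """phi_s / rho_p are undefined for two-part compositions.

    For D = 2 every clr row is (c, -c), so the denominator variance
    var(c_j + c_k) is identically zero.
    """


class UnreplaceableRowError(LatticeCodaError, ValueError):
    """A row of all zeros carries no relative information to preserve."""


class SpecError(LatticeCodaError, ValueError):
    """A replacement specification is out of its valid domain."""
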