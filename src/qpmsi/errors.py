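"""Exception hierarchy for the qpmsi package.

All errors raised by the library derive from :class:`QpmsiError` so callers
can catch the package's failures with a single except clause.  Solver
infeasibility is deliberately NOT an exception: it is a legitimate outcome
of a selection run and is reported through ``SelectionResult.status``.
"""


class QpmsiError(Exception):
    """Base class for all qpmsi errors."""


class ZeroVarianceTrait(QpmsiError):
    """A trait column has zero dispersion and cannot be standardized."""

    def __init__(self, trait_names):
        self.trait_names = list(trait_names)
        super().__init__(
            f"trait(s) with zero variance cannot be standardized: {self.trait_names}"
        )


class MissingValue(QpmsiError):
    """A non-finite cell was found where a finite value is required."""


class LengthMismatch(QpmsiError):
    """A per-trait parameter vector does not match the number of traits."""


class NegativeGain(QpmsiError):
    """A minimum-gain percentage R_j is negative."""


class InvalidSize(QpmsiError):
    """The selection size s is outside [1, n]."""


class MonomorphicMarker(QpmsiError):
    """Marker column(s) with zero variance under column standardization."""

    def __init__(self, marker_names):
        self.marker_names = list(marker_names)
        super().__init__(
            f"monomorphic marker(s) cannot be scaled: {self.marker_names[:10]}"
            + ("..." if len(self.marker_names) > 10 else "")
        )


class DimensionError(QpmsiError):
    """Empty or dimensionally inconsistent input."""


class AsymmetricMatrix(QpmsiError):
    """A relationship matrix departs from symmetry beyond tolerance."""


class IDMismatch(QpmsiError):
    """Genotype identifier sets do not agree across inputs."""


class CapExceeded(QpmsiError):
    """Brute-force enumeration would exceed the configured subset cap."""


class EmptySelection(QpmsiError):
    """Metrics requested for a result that selected no genotypes."""


class InvalidConfig(QpmsiError):
    """A simulation or run configuration violates its invariants."""


class NonPSDCorrelation(QpmsiError):
    """A target trait-correlation matrix is not positive semidefinite."""


class ParseError(QpmsiError):
    """An input file could not be parsed as the expected dialect."""
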