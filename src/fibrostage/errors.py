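"""Exception hierarchy shared across the package."""


class FibrostageError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FibrostageError, ValueError):
    """A value violates a precondition (non-positive lab, out-of-range stage, ...)."""


class UnitError(InvalidInputError):
    """A value is numerically implausible for its declared unit.

    The canonical case is a platelet count supplied in cells/uL instead of
    10^9/L, which would silently inflate FIB-4 by three orders of magnitude.
    """


class MissingELFError(FibrostageError):
    """ELF is required by the sequential algorithm but absent for a record."""

    def __init__(self, record_id: str | None = None):
        self.record_id = record_id
        ident = record_id if record_id is not None else "<unknown>"
        super().__init__(
            f"record {ident}: FIB-4 is in the intermediate band "
            "[1.30, 2.67) and ELF is required but missing"
        )


class SeparationError(FibrostageError):
    """Logistic-regression design is perfectly (or quasi-) separated.

    Raised instead of returning silently divergent coefficients.
    """


class UndefinedMetricError(FibrostageError):
    """A metric's denominator is empty (e.g. AUC with a single-class label set)."""
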