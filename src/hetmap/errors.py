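"""Exception hierarchy shared across the package.

Every error raised deliberately by hetmap derives from :class:`HetmapError`
so callers (and the CLI) can distinguish modelling problems from bugs.
"""


class HetmapError(Exception):
    """Base class for all hetmap errors."""


class InvalidDisequilibriumError(HetmapError):
    """A (p_M, q_Q, q_q, D1, D2) combination puts a haplotype frequency
    outside [0, 1]."""


class DegenerateMarkerError(HetmapError):
    """A marker genotype class has zero population frequency, so QTL
    probabilities conditional on it are undefined."""


class UndefinedPhaseError(HetmapError):
    """Both phase configurations of a double heterozygote have zero
    probability (0/0 phase weight)."""


class InvalidParameterError(HetmapError):
    """A model parameter violates its domain (e.g. nu <= 0, |rho| >= 1)."""


class DegenerateStateError(HetmapError):
    """The ODE state is degenerate for the requested operation
    (e.g. x1 + x2 = 0 where proportions are needed)."""


class DivergenceError(HetmapError):
    """The numerical integration produced a non-finite state."""

    def __init__(self, message: str, time_reached: float | None = None):
        super().__init__(message)
        self.time_reached = time_reached


class NumericalDegeneracyError(HetmapError):
    """All mixture components underflowed for some individual."""


class NonConvergenceError(HetmapError):
    """No optimization start converged."""


class DataFormatError(HetmapError):
    """Base class for input-file problems."""


class MissingCellError(DataFormatError):
    """A (sample, time) phenotype row is absent."""


class DuplicateCellError(DataFormatError):
    """A (sample, time) phenotype row appears more than once."""


class SampleMismatchError(DataFormatError):
    """Phenotype and marker files describe different sample sets."""


class UnknownGenotypeCodeError(DataFormatError):
    """A marker genotype code is not one of MM/Mm/mm (or 2/1/0)."""


class NegativityWarning(UserWarning):
    """An integrated subpopulation size dipped below zero beyond tolerance."""
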