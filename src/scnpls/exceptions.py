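"""Exception hierarchy and CLI exit codes."""


class ScnplsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ScnplsError):
    """Invalid or inconsistent run configuration."""

    exit_code = 2


class DataError(ScnplsError):
    """Invalid input data (shape, alignment, degenerate content)."""

    exit_code = 3


class NumericalError(ScnplsError):
    """Numerical failure (SVD non-convergence, undefined statistic)."""

    exit_code = 4


class DimensionError(DataError):
    """Grids, affines or matrix shapes do not match."""


class AlignmentError(DataError):
    """Subject sets or orderings disagree between inputs."""


class DegenerateMaskError(DataError):
    """A mask selects no voxels."""


class EmptySeedError(DataError):
    """A seed sphere contains no in-mask voxels."""


class UninformativeTestError(DataError):
    """A battery column has no observed values to impute from."""


class CollinearityWarning(UserWarning):
    """Confound design is rank-deficient; minimum-norm solution used."""
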