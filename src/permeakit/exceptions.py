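"""Exception hierarchy for permeakit."""


class PermeakitError(Exception):
    """Base class for all permeakit errors."""


class InvalidParameterError(PermeakitError, ValueError):
    """A parameter is outside its admissible domain."""


class IntegrationInstabilityError(PermeakitError):
    """A Langevin step exceeded the configured displacement cap."""

    def __init__(self, step: int, displacement: float, cap: float):
        self.step = step
        self.displacement = displacement
        self.cap = cap
        super().__init__(
            f"integration instability at step {step}: |dz| = "
            f"{displacement:.4g} nm exceeds cap {cap:.4g} nm"
        )


class CoverageError(PermeakitError):
    """Data do not cover the requested bins/windows."""


class ConvergenceError(PermeakitError):
    """An iterative solver did not converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class InsufficientDataError(PermeakitError):
    """A time series is too short or degenerate for the requested estimate."""


class GridError(PermeakitError):
    """Profile grids are incompatible with the requested operation."""


class ConnectivityError(PermeakitError):
    """The discretized trajectories do not form a connected Markov chain."""


class UnreachableStateError(PermeakitError):
    """A first-passage target cannot be reached (infinite MFPT)."""


class PartitionError(PermeakitError):
    """A metastable partition lacks required structure or labels."""


class DegenerateSpectrumError(PermeakitError):
    """A rate matrix is defective; the analytic eigensolution is unavailable."""


class FitError(PermeakitError):
    """A nonlinear fit failed to converge."""


class XvgParseError(PermeakitError):
    """Malformed .xvg trajectory file."""
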