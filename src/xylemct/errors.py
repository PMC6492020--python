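"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation problems (bad inputs,
schema violations, bad configuration) exit with 2, convergence failures
with 3.
"""


class XylemCTError(Exception):
    """Base class for all package errors."""


class ValidationError(XylemCTError, ValueError):
    """Invalid argument, configuration value, or precondition violation."""


class SchemaError(ValidationError):
    """Tabular/file input does not conform to the documented schema."""


class NoDataError(ValidationError):
    """A data file or table is present but contains no usable rows."""


class PackingError(XylemCTError, RuntimeError):
    """Rejection-sampling placement could not reach the requested density."""

    def __init__(self, placed: int, requested: int, attempts: int):
        self.placed = placed
        self.requested = requested
        self.attempts = attempts
        super().__init__(
            f"conduit packing failed: placed {placed} of {requested} requested "
            f"conduits after {attempts} rejection attempts; lower the density, "
            f"shrink diameters, or enlarge the xylem region"
        )


class MatchError(XylemCTError, RuntimeError):
    """Ambiguous or impossible initial/final scan conduit matching."""


class ConvergenceError(XylemCTError, RuntimeError):
    """A curve fit or bootstrap failed to converge."""
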