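"""Exception hierarchy shared across the assessment stages."""


class DynapoolError(Exception):
    """Base class for all package errors."""


class DataFormatError(DynapoolError, ValueError):
    """A sample table is malformed (missing column, bad dialect)."""


class InsufficientDataError(DynapoolError, ValueError):
    """Too few samples (or too few distinct ages/groups) for the requested fit."""


class DegenerateInputError(DynapoolError, ValueError):
    """Input has no usable variation (e.g. zero length variance)."""


class DegenerateEstimateError(DynapoolError, ValueError):
    """An estimator hit an undefined region (e.g. mean length at or below Lc)."""


class EmptyCatchError(DynapoolError, ValueError):
    """Gear selectivity removed every simulated fish; lower Lc_gear."""


class FitError(DynapoolError, RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate found."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}
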