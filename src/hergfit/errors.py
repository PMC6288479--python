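"""Exception hierarchy shared across the package."""


class HergfitError(Exception):
    """Base class for all package errors."""


class ModelEvaluationError(HergfitError):
    """A parameter/voltage combination produced a non-finite rate."""


class SimulationError(HergfitError):
    """The forward simulation failed (solver breakdown, conservation loss).

    Inference treats this as a zero-probability parameter set.
    """


class OracleInapplicableError(HergfitError):
    """The analytic constant-voltage solution does not apply (initial state
    is not a product of activation and recovery gates)."""


class SpecError(HergfitError):
    """A fitting specification failed validation."""


class DataError(HergfitError):
    """A data table failed validation."""


class BindingError(HergfitError):
    """Spec, data, model and protocol could not be bound into a problem."""
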