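"""Exception hierarchy shared across the pipeline."""


class EpifractError(Exception):
    """Base class for all pipeline errors."""


class ContractError(EpifractError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class DegenerateInputError(EpifractError, ValueError):
    """Input is formally valid but carries no usable signal (empty, constant...)."""


class CoreNotEvaluableError(EpifractError):
    """No threshold of the sweep produced a defined fractal-dimension estimate."""


class InsufficientDataError(EpifractError, ValueError):
    """Too few observations (or degenerate quantiles) for the requested statistic."""


class UndefinedEstimateError(EpifractError):
    """A fit could not be formed (too few scales, zero counts, no variation)."""
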