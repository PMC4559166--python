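"""Exception types shared across the pipeline."""


class EvotraceError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(EvotraceError, ValueError):
    """An argument violates a documented precondition."""


class ConflictError(EvotraceError, ValueError):
    """Mutually incompatible inputs (e.g. overlapping planted events)."""


class DataIntegrityError(EvotraceError, ValueError):
    """Input data violates an internal consistency invariant."""


class InsufficientDataError(EvotraceError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateDataError(EvotraceError, ValueError):
    """Zero-variance or otherwise degenerate input for a statistic."""
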