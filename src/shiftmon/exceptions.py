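"""Exception hierarchy for shiftmon."""


class ShiftmonError(Exception):
    """Base class for all shiftmon errors."""


class ConfigurationError(ShiftmonError, ValueError):
    """A configuration object is invalid; the message names the offending field."""


class DegenerateDataError(ShiftmonError, ValueError):
    """Input lacks the structure a metric needs (e.g. a single outcome class)."""


class InvalidTargetError(ShiftmonError, ValueError):
    """A requested resampling target cannot be reached (e.g. thinning upward)."""


class ConvergenceError(ShiftmonError, RuntimeError):
    """An iterative fit failed to converge within the iteration budget."""


class UndefinedStatisticError(ShiftmonError, ValueError):
    """A test statistic is undefined for the given inputs (e.g. zero SEs)."""


class PipelineError(ShiftmonError, RuntimeError):
    """A monitoring-pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
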