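"""Exception hierarchy for the pipeline."""


class AccelethogramError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AccelethogramError, ValueError):
    """A scalar argument is outside its documented domain."""


class InvalidWindowError(InvalidArgumentError):
    """A smoothing/summary window is shorter than the minimum (2 samples)."""


class InvalidMixError(InvalidArgumentError):
    """Non-background behaviour fractions sum to >= 1."""


class InvalidMaskError(AccelethogramError, ValueError):
    """Label-mask intervals overlap; message lists the offending pairs."""


class InsufficientDataError(AccelethogramError, ValueError):
    """Input series too short for the requested transform."""


class MalformedInputError(AccelethogramError, ValueError):
    """An input file violates its schema (cadence, columns, values)."""


class DegenerateTrainingError(AccelethogramError, ValueError):
    """Training data contains fewer than two behaviour classes."""


class InvalidContextError(AccelethogramError, ValueError):
    """Contextual metadata is inconsistent (e.g. dawn and dusk overlap)."""
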