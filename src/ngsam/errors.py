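"""Exception hierarchy for pipeline failures.

Failures that correspond to a real experiment failing (rather than to a
misconfiguration) carry a ``stage`` label so that grid runners can record the
failure mode instead of aborting.
"""


class NgsamError(Exception):
    """Base class for all package errors."""


class ParameterError(NgsamError, ValueError):
    """Invalid parameter value (non-positive size, rate outside [0, 1], ...)."""


class ConfigurationError(NgsamError):
    """A configured limit was exceeded, e.g. the genealogy sample cap."""


class ExperimentFailure(NgsamError):
    """A simulated experiment failed at some protocol/analysis stage."""

    stage: str = "unknown"

    def __init__(self, message: str = ""):
        super().__init__(message or self.stage)


class ProtocolFailure(ExperimentFailure):
    """No molecules survived a dilution step ("empty_sample")."""

    stage = "empty_sample"


class AssemblyFailure(ExperimentFailure):
    """No contig of the required minimum length could be assembled."""

    stage = "assembly"


class StrandednessFailure(ExperimentFailure):
    """A contig could not be oriented against the longest contig."""

    stage = "strandedness"


class AmbiguousAlignmentFailure(ExperimentFailure):
    """The consensus did not align unambiguously to the target."""

    stage = "alignment_ambiguous"


class CalibrationError(NgsamError):
    """Bisection bounds failed to bracket the calibration target."""
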