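"""Exception hierarchy shared across the analysis chain.

Every failure mode that callers are expected to branch on gets its own class;
all inherit from :class:`PulsewaveError` so a pipeline can catch one base.
"""


class PulsewaveError(Exception):
    """Base class for all pulsewave errors."""


class ParameterError(PulsewaveError, ValueError):
    """Invalid simulation or configuration parameter (names the field)."""


class SchemaError(PulsewaveError, ValueError):
    """Input file is missing a required column or has a malformed header."""


class UnitError(PulsewaveError, ValueError):
    """Declared physical unit is not one of the supported units."""


class SamplingError(PulsewaveError, ValueError):
    """Time grid is non-uniform or the sampling rate is inconsistent."""


class LengthError(PulsewaveError, ValueError):
    """Series too short for the requested operation."""


class DetectionError(PulsewaveError, RuntimeError):
    """Beat detection found fewer than two feet (or no extrema at all)."""


class GroupingError(PulsewaveError, ValueError):
    """Not enough beats to form a complete ensemble group."""


class WindowError(PulsewaveError, RuntimeError):
    """Too few samples in the early-systolic impedance fit window."""


class FitError(PulsewaveError, RuntimeError):
    """Degenerate or non-physical regression fit (e.g. non-positive slope)."""


class ShapeError(PulsewaveError, ValueError):
    """Paired series have mismatched lengths."""


class DegenerateBeatError(PulsewaveError, RuntimeError):
    """Beat yields a non-positive systolic flow integral."""


class ClassificationError(PulsewaveError, RuntimeError):
    """No sample qualifies for a mandatory wave class (e.g. FCW)."""


class SynthesisError(PulsewaveError, RuntimeError):
    """Pressure-only flow synthesis failed (missing notch or diastolic peak)."""


class AggregationError(PulsewaveError, RuntimeError):
    """No valid beats left to aggregate."""


class SessionError(PulsewaveError, RuntimeError):
    """Recording cannot support a complete analysis session."""


class InternalConsistencyError(PulsewaveError, RuntimeError):
    """A quantity violated an internal identity beyond numerical tolerance."""
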