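"""Exception and warning hierarchy.

Every error raised by this package derives from :class:`NeoEitError` so
pipeline code can isolate per-subject failures with a single except clause.
"""


class NeoEitError(Exception):
    """Base class for all neoeit errors."""


class ValidationError(NeoEitError, ValueError):
    """A domain invariant was violated (message names the offending field)."""


class SchemaError(NeoEitError, ValueError):
    """A file is missing required fields/columns."""


class CorruptionError(NeoEitError, OSError):
    """Sidecar metadata and frame payload disagree."""


class GeometryError(NeoEitError, ValueError):
    """Lung ROI geometry is impossible (overlap, out of grid)."""


class ParameterError(NeoEitError, ValueError):
    """A scenario/config parameter combination is inconsistent."""


class StateError(NeoEitError, RuntimeError):
    """Operation applied in the wrong state (e.g. double normalization)."""


class BoundsError(NeoEitError, IndexError):
    """Requested window falls outside the recording."""


class ArtefactError(NeoEitError, RuntimeError):
    """Segment failed the artefact screen and hard failure was requested."""


class InsufficientBreathsError(NeoEitError, RuntimeError):
    """Fewer than two complete breaths detected in the segment."""


class DegenerateOutcomeError(NeoEitError, ValueError):
    """Outcome vector has a single class."""


class CollinearityError(NeoEitError, ValueError):
    """Design matrix is rank deficient."""


class UndefinedRatioError(NeoEitError, ZeroDivisionError):
    """A ratio metric has a zero denominator (reported, never inf)."""


class DegenerateSignalWarning(UserWarning):
    """All-zero pixel map; metric returned its degenerate value."""


class ArtefactWarning(UserWarning):
    """Segment flagged artefactual by the robust-z screen."""


class SmallSampleWarning(UserWarning):
    """Fit attempted with fewer events/observations than recommended."""
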