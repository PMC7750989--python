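"""Exception hierarchy for gulpflow.

All pipeline-facing errors derive from :class:`GulpflowError` so the study
driver can record a per-trial failure and continue with the remaining trials.
"""


class GulpflowError(Exception):
    """Base class for all gulpflow errors."""


class FormatError(GulpflowError):
    """A file's header or layout does not match the declared dialect."""


class ParseError(GulpflowError):
    """A file is structurally unreadable (ragged rows, non-numeric cells)."""


class ValidationError(GulpflowError):
    """A value violates a domain constraint (unknown food type, bad config)."""


class ConfigError(GulpflowError):
    """Study or generator configuration is invalid or infeasible."""


class InsufficientMarkersError(GulpflowError):
    """Fewer than three usable marker correspondences in a frame."""


class DegenerateGeometryError(GulpflowError):
    """Point configuration is rank-deficient (collinear markers, flat SVD)."""


class AlignmentError(GulpflowError):
    """Two per-frame series that must be index-aligned have different lengths."""


class NoIntersectionError(GulpflowError):
    """The rostrocaudal axis ray does not pierce the esophageal plane."""


class EmptySeriesError(GulpflowError):
    """An operation received a series with no usable (non-gap) samples."""


class InsufficientLengthError(GulpflowError):
    """Series too short for the trimmed structural-change candidate window."""


class NoBreakpointError(GulpflowError):
    """Structural-change test did not reach the required significance level."""
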