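"""Exception hierarchy shared by all pipeline stages."""


class GaitNirsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitNirsError):
    """Invalid parameters, montage/ground-truth mismatch, singular matrices."""


class InvalidDesignError(GaitNirsError):
    """Task design is degenerate or inconsistent with the recording."""


class InvalidInputError(GaitNirsError):
    """A numeric input violates a precondition (empty window, empty cohort...)."""


class InvalidSignalError(GaitNirsError):
    """A time series violates a physical constraint (non-positive intensity)."""


class InvalidMetadataError(GaitNirsError):
    """Subject metadata is missing a required field."""


class InvalidSubjectError(GaitNirsError):
    """Subject-level aggregation is impossible (e.g. empty hemisphere)."""


class SchemaError(GaitNirsError):
    """A table is missing required columns or violates uniqueness."""


class FormatError(GaitNirsError):
    """An on-disk recording or sidecar is malformed."""
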