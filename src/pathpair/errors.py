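"""Exception hierarchy.

Every error raised by the package derives from :class:`PathpairError` so
callers can catch a single base class at pipeline boundaries.
"""


class PathpairError(Exception):
    """Base class for all pathpair errors."""


class ValidationError(PathpairError):
    """Input data violates a structural invariant (negative counts, empty file, ...)."""


class MetadataError(PathpairError):
    """Feature metadata (bond level / entity kind sidecar) is missing or inconsistent."""


class PartitionError(PathpairError):
    """A bond-level partition does not cover the matrix columns exactly once."""


class RangeError(PathpairError):
    """Supplied min-max scaling ranges do not cover every column."""


class ShapeError(PathpairError):
    """Matrix widths or column orderings do not match."""


class MissingMemberError(PathpairError):
    """A pathway membership references a metabolite id absent from the matrix."""


class NamingError(PathpairError):
    """Entry-id collision between metabolite and pathway identifiers."""


class StratificationError(PathpairError):
    """A (pathway, label) stratum is too small to split."""


class BalanceError(PathpairError):
    """A training set is missing one of the two classes."""


class UnsupportedModelError(PathpairError):
    """Operation defined only for one classifier backend (e.g. gain importance)."""


class TuningError(PathpairError):
    """Hyperparameter search produced no usable trial."""


class AggregationError(PathpairError):
    """Feature-importance aggregation received no usable input."""


class InsufficientPairsError(PathpairError):
    """Too few shared atom colors to correlate metabolite vs pathway importances."""


class ConstraintError(PathpairError):
    """Results-store uniqueness or check constraint violated."""


class ConfigError(PathpairError):
    """Simulation or encoder configuration violates its invariants."""
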