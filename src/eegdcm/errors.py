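"""Exception hierarchy shared across the package."""


class EegDcmError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(EegDcmError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(EegDcmError, ValueError):
    """Runtime input (data, table, vector) violates an operation precondition."""


class ShapeError(EegDcmError, ValueError):
    """Array dimensions are inconsistent."""


class StabilityError(EegDcmError, ValueError):
    """A dynamical system matrix has an eigenvalue with non-negative real part."""


class BoundaryError(EegDcmError, ValueError):
    """An epoch window falls outside the recording."""


class NumericalRankError(EegDcmError, ValueError):
    """A linear system is numerically rank-deficient."""


class CoverageError(EegDcmError, ValueError):
    """An ROI sphere contains no sources."""


class LookupError_(EegDcmError, KeyError):
    """An unknown label was requested."""


class ExcludedEdgeError(EegDcmError, ValueError):
    """A coupling edge is missing from one of the streams being compared."""


class IntegrityError(EegDcmError, ValueError):
    """Cross-referenced records (blocks vs responses) do not line up."""


class InvalidDesignError(EegDcmError, ValueError):
    """A statistical design is degenerate (e.g. a single group)."""


class DegenerateEvidenceError(EegDcmError, ValueError):
    """All model evidences are -inf; posteriors are undefined."""


class UnrecoverableChannelsError(EegDcmError, ValueError):
    """Every channel is marked bad; interpolation impossible."""
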