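"""Exception hierarchy for steerpmf.

Every error raised by the package derives from :class:`SteerpmfError` so callers
can catch pipeline failures with a single except clause.
"""


class SteerpmfError(Exception):
    """Base class for all steerpmf errors."""


class DegenerateGeometryError(SteerpmfError):
    """A distance gradient was requested for an atom pair at zero separation."""


class UnknownSystemError(SteerpmfError, KeyError):
    """A model-system name was not recognized by the factory."""


class IntegrationFailureError(SteerpmfError):
    """The integrator produced a non-finite state; message names the step."""


class UnsupportedOracleError(SteerpmfError):
    """An exact free-energy oracle was requested for a non-separable system."""


class InsufficientSnapshotsError(SteerpmfError):
    """The restrained pre-run is too short for the requested snapshot count."""


class ProtocolValidationError(SteerpmfError, ValueError):
    """A steering protocol violates its invariants (e.g. duplicate seeds)."""


class DataValidationError(SteerpmfError, ValueError):
    """Input data (work matrices, trajectories) contain invalid values."""


class InsufficientReplicatesError(SteerpmfError, ValueError):
    """Bias correction needs at least two replicate work functions."""


class ConfigValidationError(SteerpmfError, ValueError):
    """A pipeline configuration violates the schema; message names the field."""
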