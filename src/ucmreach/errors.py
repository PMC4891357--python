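"""Exception hierarchy for the package.

All errors derive from :class:`UcmReachError` so callers can catch the
package's failures with a single clause while still distinguishing the
common failure modes (bad inputs, too little data, detection failures,
kinematic infeasibility).
"""


class UcmReachError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(UcmReachError, ValueError):
    """An argument violates a documented precondition (shape, finiteness...)."""


class InsufficientDataError(UcmReachError, ValueError):
    """Fewer samples/trials than the operation requires."""


class DetectionFailureError(UcmReachError):
    """Movement start or end could not be located in a trajectory.

    ``which`` is ``"start"`` or ``"end"``.
    """

    def __init__(self, which: str, message: str = ""):
        self.which = which
        super().__init__(message or f"movement {which} not found")


class ReachabilityError(UcmReachError):
    """A requested tip position lies outside the arm's reachable workspace."""


class ConvergenceError(UcmReachError):
    """Iterative inverse kinematics failed to reach the residual tolerance."""


class ConfigError(UcmReachError):
    """The pipeline configuration file is missing or malformed."""
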