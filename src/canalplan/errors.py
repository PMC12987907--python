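"""Exception hierarchy for the planning pipeline.

All errors derive from :class:`CanalPlanError` so callers can catch the
package's failures with a single except clause; per-stage failures in the
cohort runner are isolated at that level.
"""


class CanalPlanError(Exception):
    """Base class for all canalplan errors."""


class ParameterError(CanalPlanError, ValueError):
    """An input parameter violates its documented invariant."""


class GeometryError(CanalPlanError):
    """A geometric construction failed (degenerate or empty result)."""


class TopologyError(CanalPlanError):
    """A skeleton or graph has the wrong topology (empty, heavily branched)."""


class ConvergenceError(CanalPlanError):
    """An iterative procedure did not converge within its iteration cap."""

    def __init__(self, message, last_residual=None):
        super().__init__(message)
        self.last_residual = last_residual


class OutOfBoundsError(CanalPlanError):
    """A query point fell outside a distance-field grid (no extrapolation)."""


class CoverageError(CanalPlanError):
    """Too many entry-region samples failed to project onto the surface."""


class ConfigurationError(CanalPlanError):
    """Inconsistent inputs to an analysis stage (e.g. missing distance field)."""


class RangeError(CanalPlanError, ValueError):
    """A scalar argument is outside its admissible range."""
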