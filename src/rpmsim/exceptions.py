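"""Exception hierarchy for rpmsim.

All rpmsim errors derive from :class:`RpmsimError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the planning and simulation surface.
"""


class RpmsimError(Exception):
    """Base class for all rpmsim errors."""


class InvalidArgumentError(RpmsimError, ValueError):
    """A numeric argument is out of its physical or mathematical domain."""


class EmptyTraceError(RpmsimError, ValueError):
    """An operation requiring a non-empty gravity trace received an empty one."""


class UnitError(RpmsimError, ValueError):
    """A quantity was passed without a recognized unit tag."""


class GeometryError(RpmsimError, ValueError):
    """A placement request is geometrically infeasible."""


class ConfigError(RpmsimError, ValueError):
    """A run configuration is incomplete, contradictory, or has unknown keys."""
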