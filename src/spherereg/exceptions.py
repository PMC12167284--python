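"""Exception hierarchy for spherereg.

All contract violations raise :class:`SphereregError` subclasses so callers can
distinguish bad inputs from genuine numerical failures.
"""


class SphereregError(ValueError):
    """Base class for all spherereg contract errors."""


class FrameMismatchError(SphereregError):
    """Two transforms/objects were combined across incompatible coordinate frames."""


class DegenerateSilhouetteError(SphereregError):
    """Sphere is behind the camera or encloses the camera centre."""


class DegenerateConicError(SphereregError):
    """Conic is not a real ellipse where an ellipse is required."""


class InsufficientSupportError(SphereregError):
    """Too few mesh vertices support a sphere fit."""


class InitializationError(SphereregError):
    """PnP correspondence search failed to find a consistent initial pose."""
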