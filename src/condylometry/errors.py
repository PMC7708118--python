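"""Exception hierarchy.

Every failure mode named in the public contracts raises a subclass of
:class:`CondylometryError`, so callers (and the CLI) can distinguish data
problems from programming errors.
"""


class CondylometryError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(CondylometryError, ValueError):
    """A simulation or phantom specification violates its invariants."""


class LandmarkError(CondylometryError, KeyError):
    """A required landmark is missing or malformed."""


class DegenerateFrameError(CondylometryError, ValueError):
    """Reference-frame landmarks are collinear or coincident."""


class NotchDetectionError(CondylometryError, RuntimeError):
    """Automatic sigmoid-notch detection failed (supply a landmark instead)."""


class NoCondyleError(CondylometryError, RuntimeError):
    """No condylar region remains above the requested cut plane."""


class UndefinedAngleError(CondylometryError, ValueError):
    """An inclination angle is undefined (coincident projected points)."""


class VolumeError(CondylometryError, ValueError):
    """A volume was requested on a non-watertight or degenerate mesh."""


class RankDeficiencyError(CondylometryError, ValueError):
    """A cross-product matrix is singular; names the offending variables."""


class PhantomError(CondylometryError, RuntimeError):
    """Internal failure while constructing a synthetic phantom."""


class ConfigError(CondylometryError, ValueError):
    """Pipeline configuration is invalid (unknown keys, bad values)."""
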