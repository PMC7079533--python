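"""Exception hierarchy.

Every error raised by this package derives from :class:`PVShockError` so
pipeline code can distinguish domain failures from programming errors.
"""


class PVShockError(Exception):
    """Base class for all package errors."""


class InvalidPresetError(PVShockError):
    """A stage preset violates a physiological invariant."""


class SimulationFailureError(PVShockError):
    """The hemodynamic integration diverged; message names the offending parameter set."""


class InvalidCalibrationError(PVShockError):
    """Non-positive or otherwise unusable calibration inputs."""


class InsufficientDataError(PVShockError):
    """Too few beats / samples / subjects for the requested estimate."""


class DegenerateFitError(PVShockError):
    """A regression is ill-posed (parallel to identity, identical points, ...)."""


class NonPhysiologicalESPVRError(PVShockError):
    """An end-systolic pressure-volume fit produced a non-positive slope."""


class NoBeatsError(PVShockError):
    """No cardiac cycles could be detected in a trace."""


class InvalidV0Error(PVShockError):
    """Volumes at or below the unstressed volume V0 where V - V0 > 0 is required."""


class InvalidStrokeVolumeError(PVShockError):
    """Non-positive stroke volume where ejection is required."""


class DegenerateLoopError(PVShockError):
    """A pressure-volume loop with fewer than three distinct vertices."""


class InsufficientBeatsError(InsufficientDataError):
    """Fewer beats than required inside the analysis window."""


class UndefinedReferenceError(PVShockError):
    """A relative difference is undefined because a reference value is zero."""


class ModelFailureError(PVShockError):
    """Mixed-model estimation failed even after the pooled-variance fallback."""


class NonConvergenceError(PVShockError):
    """An iterative procedure did not reach its stopping criterion."""


class ConfigError(PVShockError):
    """Run-configuration validation failed; ``errors`` lists every violation."""

    def __init__(self, message: str, errors: list | None = None):
        super().__init__(message)
        self.errors = errors or []


class PipelineError(PVShockError):
    """A pipeline stage failed; message names the stage and context."""
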