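"""Exception hierarchy shared across the package.

All handled failures derive from :class:`MonofilmError` so callers (and the
CLI) can distinguish domain errors from programming errors.
"""


class MonofilmError(Exception):
    """Base class for all handled errors raised by monofilm."""


class DegenerateCurveError(MonofilmError):
    """Fewer than two samples survive monotonization."""


class PressureOutOfRangeError(MonofilmError):
    """A pressure query fell outside the sampled range (no extrapolation)."""


class NoLiftOffError(MonofilmError):
    """The curve never reaches the lift-off threshold pressure."""


class SmoothingWindowError(MonofilmError):
    """Too few samples for the requested smoothing window."""


class ConventionError(MonofilmError):
    """Per-molecule and per-lipid curves were mixed inconsistently."""


class KineticsFitError(MonofilmError):
    """Neither kinetic model order converged; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoExclusionError(MonofilmError):
    """The insertion series has non-negative slope: no exclusion pressure."""


class DegenerateThresholdError(MonofilmError):
    """Automatic thresholding failed (e.g. constant image)."""


class PackingError(MonofilmError):
    """Requested domain area fraction is unattainable with the layout."""


class SimulationParameterError(MonofilmError):
    """Generator parameters produce an inconsistent (non-monotone) curve."""
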