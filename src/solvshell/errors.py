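"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`SolvshellError`
so callers (and the CLI) can distinguish domain errors from bugs.
"""


class SolvshellError(Exception):
    """Base class for all package errors."""


class InvalidBoxError(SolvshellError):
    """Non-positive or otherwise unusable periodic box."""


class EmptySelectionError(SolvshellError):
    """An atom selection that must be non-empty was empty."""


class DegeneratePlaneError(SolvshellError):
    """Plane fit requested for collinear (or <3) atoms."""


class TrajectoryFormatError(SolvshellError):
    """Unparseable trajectory/topology file or unknown extension."""


class AtomCountMismatchError(TrajectoryFormatError):
    """Frame atom count disagrees with earlier frames or the topology."""


class TopologyError(SolvshellError):
    """Topology invariant violated (molecule composition, roles, ...)."""


class PackingFailureError(SolvshellError):
    """Solvent-box builder could not place the requested molecule count."""


class GeometryError(SolvshellError):
    """Requested pose/geometry is unrealizable."""


class AnalysisWindowError(SolvshellError):
    """Discard window leaves no frames to analyze."""


class InvalidSwitchError(SolvshellError):
    """Switching function with r_on >= r_off."""


class SingularPairError(SolvshellError):
    """Pair energy at zero separation."""


class InsufficientDataError(SolvshellError):
    """Too little data for the requested estimate (e.g. short trajectory)."""


class DegenerateFrameError(SolvshellError):
    """A frame cannot enter an ensemble average (e.g. no bulk water)."""


class InvalidBinningError(SolvshellError):
    """Non-positive bin width or impossible histogram request."""


class InvalidWindowError(SolvshellError):
    """Smoothing window incompatible with the data length."""


class FeatureNotFoundError(SolvshellError):
    """A required RDF feature (extremum / unity crossing) is absent."""

    def __init__(self, feature: str, message: str | None = None):
        self.feature = feature
        super().__init__(message or f"RDF feature not found: {feature}")


class FitFailureError(SolvshellError):
    """Nonlinear fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DomainError(SolvshellError):
    """Quadrature/evaluation requested outside the data's support."""


class InvalidDensityError(SolvshellError):
    """Negative number density."""


class InvalidSoftCoreError(SolvshellError):
    """Negative soft-core alpha parameter."""


class ScheduleError(SolvshellError):
    """Lambda schedule unordered or otherwise invalid."""


class ConfigError(SolvshellError):
    """Pipeline configuration invalid; carries the full error list."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
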