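"""Exception types shared across the package."""


class PedscrewError(Exception):
    """Base class for all package-specific errors."""


class FrameMismatchError(PedscrewError):
    """Operands are expressed in different coordinate frames."""


class DegenerateGeometryError(PedscrewError):
    """Input geometry is degenerate (collinear landmarks, coplanar cloud, ...)."""


class FitError(PedscrewError):
    """A least-squares fit failed or did not converge."""


class AmbiguousOrientationError(PedscrewError):
    """Axis orientation cannot be disambiguated against the plan."""


class UndefinedStatisticError(PedscrewError):
    """A statistic is undefined for the given input (degenerate marginals, ...)."""
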