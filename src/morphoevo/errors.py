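"""Exception hierarchy shared across the package."""


class MorphoEvoError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MorphoEvoError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class DegenerateGeometryError(MorphoEvoError, ArithmeticError):
    """A computation hit a numerically degenerate configuration
    (collinear landmarks, coincident curve neighbours, singular covariance)."""


class DegenerateDataError(MorphoEvoError, ArithmeticError):
    """The data admit no meaningful estimate (e.g. zero residual variance)."""


class NewickParseError(MorphoEvoError, ValueError):
    """Malformed Newick input."""


class ConvergenceWarning(UserWarning):
    """An iterative routine stopped before reaching its tolerance."""
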