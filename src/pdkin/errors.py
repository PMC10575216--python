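"""Exception hierarchy for pdkin.

Every error raised on a contract violation derives from :class:`PdkinError`
so callers can catch the package's failures with a single except clause,
while still subclassing the closest builtin (``ValueError`` etc.).
"""


class PdkinError(Exception):
    """Base class for all pdkin errors."""


class InvalidArgumentError(PdkinError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(PdkinError, ValueError):
    """A file does not parse under the expected dialect."""


class ValidationError(PdkinError, ValueError):
    """Input data violates a structural invariant (missing marker, item, ...)."""


class UnrecoverableGapError(PdkinError, ValueError):
    """A channel has fewer than two observed samples; gaps cannot be filled."""


class InsufficientGaitError(PdkinError, RuntimeError):
    """Too few gait events to compute spatiotemporal parameters."""


class DegenerateGeometryError(PdkinError, ValueError):
    """Coincident marker positions make a joint angle undefined."""


class InfeasibleSplitError(PdkinError, ValueError):
    """Dataset is too small or unbalanced for the requested split scheme."""


class DegenerateFoldError(PdkinError, ValueError):
    """A training fold contains a single class."""


class InfeasibleExperimentError(PdkinError, RuntimeError):
    """Filtering left fewer than two classes; the experiment cannot run."""


class UnsupportedModelError(PdkinError, TypeError):
    """Operation requires a tree-ensemble model exposing impurity decreases."""


class SchemaError(PdkinError, ValueError):
    """A configuration file does not validate against the schema."""
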