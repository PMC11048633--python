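"""Exception hierarchy shared across the package."""


class WetlandNBNError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WetlandNBNError, ValueError):
    """A table, DAG or scenario file violates the expected schema."""


class TableValueError(WetlandNBNError, ValueError):
    """A trait-table cell holds an out-of-range or missing value."""


class GraphError(WetlandNBNError, ValueError):
    """The metamodel DAG is structurally invalid (cycle, bad sink, ...)."""


class ScenarioError(WetlandNBNError, ValueError):
    """A scenario definition is logically invalid."""


class DegenerateMarginalError(WetlandNBNError, ValueError):
    """All observations of a variable are identical: no marginal information."""


class FitError(WetlandNBNError, RuntimeError):
    """Model calibration failed (e.g. non-positive-definite dependence)."""
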