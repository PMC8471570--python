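"""Exception types shared across the package."""


class ScaffoldNetError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(ScaffoldNetError):
    """A lattice specification cannot produce valid geometry."""


class STLFormatError(ScaffoldNetError):
    """An STL file is malformed or truncated."""


class TopologyError(ScaffoldNetError):
    """A mesh is not watertight, so parity rasterization is undefined."""


class ShapeError(ScaffoldNetError):
    """Array shapes are inconsistent with the configured pipeline."""


class StackGapError(ScaffoldNetError):
    """A slice stack directory is missing one or more slice indices."""


class DegenerateScaleError(ScaffoldNetError):
    """A target column is constant, so min-max scaling is undefined."""


class SolverError(ScaffoldNetError):
    """The sparse elasticity solve did not converge."""
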