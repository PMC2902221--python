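"""Exception hierarchy used across the package."""


class LoopCghError(Exception):
    """Base class for all loopcgh errors."""


class InvalidArgumentError(LoopCghError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(LoopCghError):
    """An input file does not conform to the expected dialect."""


class DataError(LoopCghError):
    """Input values are structurally valid but unusable (e.g. non-positive intensity)."""


class DesignConsistencyError(LoopCghError):
    """Hybridization design sheet is internally inconsistent."""


class PlacementError(LoopCghError):
    """A random interval placement could not be satisfied."""


class AnalysisError(LoopCghError):
    """A statistical analysis cannot be carried out on the given input."""
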