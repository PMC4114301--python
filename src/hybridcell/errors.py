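"""Exception hierarchy."""


class HybridCellError(Exception):
    """Base class for all package errors."""


class SWCParseError(HybridCellError):
    """Malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class HocParseError(HybridCellError):
    """Malformed hoc-subset input."""


class MorphologyStructureError(HybridCellError):
    """Graph-level violation: multiple roots, cycles, dangling parents."""


class ConfigError(HybridCellError):
    """Invalid configuration value or unknown option."""


class MeshingError(HybridCellError):
    """Surface/volume mesh generation failure."""


class SolverError(HybridCellError):
    """Numerical failure (divergence, Newton non-convergence, ...)."""


class FullBlockageError(HybridCellError):
    """Obstacle occludes the full compartment diameter; the 1D axial
    resistance is undefined (d_new = 0) and is refused rather than guessed."""
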