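"""Exception hierarchy shared across the package."""


class StimcoilError(Exception):
    """Base class for all package errors."""


class InvalidGaugeError(StimcoilError):
    """AWG number outside the supported 0-40 range."""


class ConfigError(StimcoilError):
    """Device configuration is malformed or fails schema validation."""


class SingularityError(StimcoilError):
    """Field evaluation requested on (or within 1 nm of) a source filament."""


class GridMismatchError(StimcoilError):
    """Two field maps do not share a compatible grid (step / extent)."""


class DegenerateCorrelationError(StimcoilError):
    """Cross-correlation alignment is undefined (constant or all-zero map)."""


class MeshError(StimcoilError):
    """Mesh generation failed (self-intersecting or degenerate geometry)."""


class SolverError(StimcoilError):
    """Finite-element system is singular or inconsistent."""


class FormatError(StimcoilError):
    """Scan file is malformed (missing headers, bad rows)."""


class ScalingError(StimcoilError):
    """Current scaling is undefined (zero-current source scan)."""


class ReportError(StimcoilError):
    """Comparison report cannot be built (e.g. no active record)."""


class DataError(StimcoilError):
    """Numerical input data violates a precondition (e.g. non-positive times)."""
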