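"""Exception hierarchy for skelimpute."""


class SkelimputeError(Exception):
    """Base class for all package errors."""


class FormatError(SkelimputeError):
    """Malformed file header or unparseable content."""


class ShapeError(SkelimputeError):
    """Array or column-count inconsistency."""


class EmptyInputError(SkelimputeError):
    """Zero frames, empty sample list, or empty mask where data is required."""


class ConfigError(SkelimputeError):
    """Invalid configuration value; message names the offending field."""


class DegeneratePoseError(SkelimputeError):
    """Heading vector of zero length; rotation cannot be defined."""


class UndefinedMetricError(SkelimputeError):
    """Metric requested on zero masked cells (N = 0)."""


class TrainingDivergedError(SkelimputeError):
    """Loss became non-finite during optimization."""
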