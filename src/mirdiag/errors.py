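"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`mirdiag.cli`).
"""


class MirdiagError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirdiagError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(MirdiagError):
    """Malformed input data (non-finite Ct, unknown subtype, bad table)."""


class MissingDataError(MirdiagError):
    """A required assay or column is absent for a sample."""


class InsufficientDataError(MirdiagError):
    """Not enough samples/replicates/groups to carry out a computation."""


class DegenerateModelError(MirdiagError):
    """A class-conditional Gaussian cannot be fitted (zero variance)."""


class ThresholdSolveError(MirdiagError):
    """The posterior-odds equation has no admissible root."""
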