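"""Exception hierarchy.

All package errors derive from :class:`LovspecError` so callers (and the CLI)
can distinguish usage/configuration problems from data problems.
"""


class LovspecError(Exception):
    """Base class for all lovspec errors."""


class ConfigurationError(LovspecError):
    """Invalid configuration value (bad dwell time, missing energy class...)."""


class UsageError(LovspecError):
    """A function was called with inconsistent arguments."""


class FormatError(LovspecError):
    """A file could not be parsed, or frames disagree on the atom roster."""


class DefinitionError(LovspecError):
    """An atom selector or distance definition does not resolve."""


class GeometryError(LovspecError):
    """A geometric precondition failed (collinear atoms, too few fit atoms)."""


class DegenerateInputError(LovspecError):
    """Input carries no usable signal (e.g. zero-variance feature set)."""


class CoverageError(LovspecError):
    """A spectral grid is too narrow to hold the computed lineshape."""


class NormalizationError(LovspecError):
    """A spectrum cannot be normalized (all-zero intensities)."""
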