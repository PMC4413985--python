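"""Exception hierarchy.

All package errors derive from :class:`TUDecayError` so callers (and the CLI)
can distinguish data/configuration problems (exit code 1) from usage errors
(exit code 2, handled by click).
"""


class TUDecayError(Exception):
    """Base class for all tudecay errors."""


class FormatError(TUDecayError):
    """Malformed on-disk input (missing column, illegal character, ...)."""


class ConfigError(TUDecayError):
    """Invalid configuration or parameter value."""


class DataError(TUDecayError):
    """Inputs are well-formed but inconsistent or insufficient."""


class KineticsError(TUDecayError):
    """Physically impossible kinetic parameters (e.g. k <= 0)."""


class NormalizationError(TUDecayError):
    """Normalization cannot proceed (e.g. no usable spike-in signal)."""


class GenerationError(TUDecayError):
    """Synthetic sequence generation failed for a specific gene."""
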