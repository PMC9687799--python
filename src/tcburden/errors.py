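"""Exception hierarchy for tcburden.

All package-specific failures derive from :class:`TcBurdenError` so callers
(and the CLI) can catch one base class.
"""


class TcBurdenError(Exception):
    """Base class for all tcburden errors."""


class FormatError(TcBurdenError):
    """Malformed input file (bad delimiter layout, duplicate IDs, non-numeric cells)."""


class ConfigError(TcBurdenError):
    """Invalid configuration (overlapping cutoff bands, bad fractions, ...)."""


class DomainError(TcBurdenError):
    """A value outside the mathematical domain of an operation (e.g. log of 0)."""


class DegenerateRangeError(TcBurdenError):
    """min-max scaling requested on an all-equal vector (range is zero)."""


class ConsistencyError(TcBurdenError):
    """Inputs that must describe the same objects disagree (missing profiles, samples...)."""
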