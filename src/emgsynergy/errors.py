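"""Exception hierarchy for emgsynergy.

All package-specific failures derive from :class:`EmgSynergyError` so callers
can catch one base class at pipeline boundaries.
"""


class EmgSynergyError(Exception):
    """Base class for all emgsynergy errors."""


class ConfigurationError(EmgSynergyError):
    """A layout, manifest or parameter configuration is invalid."""


class ParseError(EmgSynergyError):
    """A data file could not be parsed (carries file/line context)."""


class SamplingRateError(EmgSynergyError):
    """Sampling rate incompatible with the requested filter passband."""


class DegenerateChannelError(EmgSynergyError):
    """A channel has zero session maximum and cannot be normalized."""


class DegenerateSegmentError(EmgSynergyError):
    """A motion segment is too short to resample."""


class DomainError(EmgSynergyError):
    """Matrix input violates non-negativity or shape requirements."""


class OrderError(EmgSynergyError):
    """Requested synergy count is incompatible with the channel count."""


class UndefinedStatisticError(EmgSynergyError):
    """A statistic (VAF, correlation) is undefined on degenerate input."""
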