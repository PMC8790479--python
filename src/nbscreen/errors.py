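"""Exception types raised by nbscreen."""


class NBScreenError(Exception):
    """Base class for all nbscreen errors."""


class ConfigError(NBScreenError):
    """A shipped or user-supplied configuration document is invalid."""


class CalibrationError(NBScreenError):
    """Reference-range quantile calibration is infeasible."""


class ProfileError(NBScreenError):
    """A disease profile cannot be constructed for the requested rule group."""


class ReportError(NBScreenError):
    """Summary arithmetic was requested on degenerate inputs."""
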