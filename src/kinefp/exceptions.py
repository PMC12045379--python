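"""Package-wide exception types."""


class KinefpError(Exception):
    """Base class for all kinefp errors."""


class ConfigError(KinefpError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class InsufficientDataError(KinefpError, ValueError):
    """Too few observations for the requested fit or classification."""


class OvercrowdedFieldError(KinefpError, ValueError):
    """Spot layout cannot satisfy the minimum-separation constraint."""
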