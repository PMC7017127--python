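"""Exception types shared across the package."""


class LglwgsError(Exception):
    """Base class for package errors."""


class ConfigurationError(LglwgsError):
    """Invalid simulation or run configuration."""


class InputError(LglwgsError):
    """Malformed or inconsistent user-supplied input table/track."""


class VcfFormatError(LglwgsError):
    """A VCF lacks a field the analysis requires (GL/PL, AD, DP)."""
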