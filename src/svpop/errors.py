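"""Exception types shared across svpop."""


class SvpopError(Exception):
    """Base class for all svpop errors."""


class ConfigurationError(SvpopError):
    """A configuration field is missing, out of range, or inconsistent."""


class VcfRecordError(SvpopError):
    """A VCF record is malformed (e.g. missing SVTYPE or END)."""
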