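"""Exception hierarchy shared across the pipeline stages."""


class PatseqError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PatseqError):
    """A parameter set violates its documented invariants."""


class InputError(PatseqError):
    """An input file or record is malformed or internally inconsistent."""
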