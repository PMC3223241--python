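"""Exception hierarchy. The CLI maps InputError to exit code 2 and
ConfigError to exit code 3."""


class BaculoannotError(Exception):
    """Base class for all package errors."""


class InputError(BaculoannotError):
    """Malformed or unsupported input data."""


class UnsupportedInputError(InputError):
    """Input is well-formed but outside the supported scope
    (e.g. multi-record GenBank files)."""


class GeneNotFoundError(InputError, KeyError):
    """A named gene is absent from a record's features."""


class ConfigError(BaculoannotError):
    """Invalid configuration (bad motif pattern, infeasible simulation...)."""


class FeasibilityError(ConfigError):
    """A simulation configuration cannot be realised
    (e.g. planted features exceed the genome length)."""
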