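"""Exception hierarchy.

ConfigurationError covers invalid parameters and config files (CLI exit
code 2); DataError covers problems with the data being analysed, such as a
zero normalizer or a missing category (CLI exit code 3).
"""


class PirnakitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PirnakitError):
    """Invalid configuration: bad parameter values, unknown keys, missing files.

    ``errors`` holds every violation found, not just the first.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DataError(PirnakitError):
    """Input data cannot be analysed as requested (e.g. zero normalizer)."""
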