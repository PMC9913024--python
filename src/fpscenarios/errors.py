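"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/validation problems (including
parse and configuration errors) exit 2; violated internal invariants exit 3.
"""


class FPScenariosError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FPScenariosError):
    """A simulation or run configuration is invalid (non-finite, out of range...)."""


class InputError(FPScenariosError):
    """User-supplied data is missing, inconsistent or out of range."""


class ParseError(InputError):
    """A tabular input file violates its schema; the message names the
    offending columns or line numbers."""


class InvariantError(FPScenariosError):
    """An internal accounting identity failed; indicates a bug, not bad input."""
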