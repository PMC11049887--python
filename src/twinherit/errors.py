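"""Exception hierarchy mapped to CLI exit codes."""


class TwinheritError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TwinheritError):
    """Malformed or inconsistent input data / configuration (exit code 2)."""

    exit_code = 2


class NumericalError(TwinheritError):
    """Numerical failure beyond the retry policy (exit code 3)."""

    exit_code = 3
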