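"""Exception taxonomy shared across the package.

Two error classes matter to callers: parameter errors (a configuration value
is out of its domain) and input errors (data handed to an operation violates
its contract). The CLI maps them to exit codes 2 and 3 respectively.
"""


class SegfuseError(Exception):
    """Base class for all package errors."""


class ParameterError(SegfuseError):
    """A configuration or tuning parameter is outside its valid domain."""


class InputError(SegfuseError):
    """Input data violates an operation's preconditions."""
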