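"""Exception hierarchy.

``ValidationError`` marks malformed input (bad table, bad config) and maps
to CLI exit code 2; any other failure maps to exit code 1.
"""


class AllomedError(Exception):
    """Base class for package errors."""


class ValidationError(AllomedError, ValueError):
    """Input data or configuration failed validation."""
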