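"""Exception hierarchy.

``InputError`` marks problems with user-supplied data or parameters
(CLI exit code 2); ``ComputationError`` marks failures arising during a
computation on otherwise valid input (CLI exit code 3).
"""


class RSimError(Exception):
    """Base class for all package-specific errors."""


class InputError(RSimError, ValueError):
    """Invalid user input: malformed files, bad parameters, broken invariants."""


class ComputationError(RSimError, RuntimeError):
    """A computation could not be completed on otherwise valid input."""
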