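"""Exception hierarchy.

The CLI maps :class:`InvalidParameterError` / :class:`EmptyDataError` to exit
code 2 and :class:`GuardExceededError` to exit code 3.
"""


class MitDbnError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MitDbnError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(MitDbnError, ValueError):
    """Input data violate a documented precondition."""


class EmptyDataError(MitDbnError, ValueError):
    """No usable observations remain after alignment/filtering."""


class NonUniformStatesError(MitDbnError, ValueError):
    """The global search requires all variables to share the same state count."""


class GuardExceededError(MitDbnError, RuntimeError):
    """A computational guard (subset count, degrees of freedom) was exceeded."""
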