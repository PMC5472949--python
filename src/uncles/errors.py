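"""Exception hierarchy.

All package-raised errors derive from :class:`UnclesError` so callers (and
the CLI) can distinguish user-facing problems from genuine bugs.
"""


class UnclesError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(UnclesError):
    """An infeasible or inconsistent design/configuration was supplied."""


class InputError(UnclesError):
    """Input data violates a documented precondition (shape, range, content)."""


class UsageError(UnclesError):
    """Operations called in the wrong order (e.g. consensus of unrelabelled partitions)."""


class FitError(UnclesError):
    """A statistical fit could not be performed (e.g. Cox model with no events)."""
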