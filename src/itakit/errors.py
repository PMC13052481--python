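"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: validation failures exit 2,
I/O failures exit 3.
"""


class ItakitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(ItakitError, ValueError):
    """Input violates a documented precondition (bad range, shape, ROI...)."""


class UnsupportedOperationError(ItakitError):
    """Operation is not defined for the requested configuration.

    Raised e.g. when inverting the Lab->RGB chain in paper-literal mode,
    whose printed forward transform is not algebraically invertible.
    """
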