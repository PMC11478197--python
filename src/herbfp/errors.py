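"""Exception hierarchy for herbfp.

``ValidationError`` subclasses ``ValueError`` so callers that only know the
standard library still catch precondition failures; the CLI maps it to exit
code 2.
"""


class HerbfpError(Exception):
    """Base class for all herbfp errors."""


class ValidationError(HerbfpError, ValueError):
    """An input violated a documented precondition."""


class NotLocatedError(HerbfpError, LookupError):
    """No chromatographic peak satisfied a localization criterion."""
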