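"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed configuration or inputs that violate a
documented contract; ``DataError`` covers well-formed files whose content is
inconsistent (missing cross-references, infeasible requests, ...).  The CLI
maps them to exit codes 1 and 2 respectively.
"""


class CgcKitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CgcKitError):
    """An input value or file violates a documented contract."""


class DataError(CgcKitError):
    """Inputs are well-formed but mutually inconsistent or infeasible."""


class UndefinedWeightError(ValidationError):
    """A relevance index was requested for a keyword with zero literature hits."""
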