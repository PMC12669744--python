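"""Exception hierarchy shared across the package."""


class PhenoloadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhenoloadError):
    """A file or table does not conform to the expected schema."""


class ValidationError(PhenoloadError):
    """Input data or configuration violates a stated constraint."""


class DegenerateInputError(PhenoloadError):
    """Input is structurally valid but too degenerate to analyse
    (e.g. a regression with fewer than three genes)."""


class UsageError(PhenoloadError):
    """The caller asked for something the inputs cannot support
    (unknown group label, empty universe, ...)."""
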