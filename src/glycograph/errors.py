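"""Exception hierarchy shared across the package."""


class GlycographError(Exception):
    """Base class for all package errors."""


class SchemaError(GlycographError):
    """An input file or table does not match the documented schema."""


class ConfigurationError(GlycographError):
    """An analysis configuration (ordering, panel, filters) is invalid."""


class IdentifierError(GlycographError, KeyError):
    """An unknown SNP, individual, or variable identifier was requested."""


class DomainError(GlycographError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class EmptyPanelError(GlycographError):
    """Quality control removed every SNP from the panel."""


class CannotImputeError(GlycographError):
    """A SNP has no observed calls, so its mean allele count is undefined."""


class CollinearityError(GlycographError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class StrandError(GlycographError):
    """Risk-allele orientation would require guessing the strand of an
    ambiguous (A/T or C/G) SNP."""
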