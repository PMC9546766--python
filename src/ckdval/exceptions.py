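"""Error hierarchy shared across the package.

Three families, mirroring who is at fault: the caller's configuration
(wrong column mapping, unknown outcome name), the data (a row violating an
invariant), or the mathematical domain of an operation (negative time,
threshold outside (0, 1)).
"""


class CKDValError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CKDValError):
    """A configuration input (mapping, rule set, model spec) is invalid."""


class DataError(CKDValError):
    """Input data violates an invariant; message names the offending row/field."""


class DomainError(CKDValError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class UndefinedResultError(CKDValError):
    """The requested statistic is undefined on this input (e.g. no comparable
    pairs for a concordance, a single-class AUC)."""
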