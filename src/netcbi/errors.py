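"""Exception hierarchy shared across the package.

The CLI maps these onto distinct process exit codes, so keep the split
between configuration, input-validation and numerical failures.
"""


class NetcbiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetcbiError):
    """A file does not match the expected layout (non-square table, bad header...)."""


class ValidationError(NetcbiError):
    """Input parsed but violates a semantic invariant (negative similarity, duplicate ID...)."""


class ParameterError(NetcbiError):
    """A numeric or grid parameter is outside its admissible range."""


class NumericalError(NetcbiError):
    """A linear solve or other numerical routine failed its accuracy contract."""


class UndefinedAUCError(NetcbiError):
    """ROC/AUC requested for a query with no positives or no negatives."""
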