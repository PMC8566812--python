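"""Exception hierarchy shared across the package."""


class MrToolsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MrToolsError):
    """Invalid user configuration (missing column, malformed config file...)."""


class ValidationError(MrToolsError):
    """Input rows violating record invariants.

    Parameters
    ----------
    message:
        Human-readable summary.
    rows:
        Zero-based indices of the offending data rows (header excluded).
    """

    def __init__(self, message: str, rows: list | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class EmptyHarmonizedSetError(MrToolsError):
    """No SNP survived harmonization for a given exposure/outcome analysis."""


class InsufficientInstrumentsError(MrToolsError):
    """An estimator was called with fewer instruments than it supports."""


class UndefinedRatioError(MrToolsError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class DegenerateDesignError(MrToolsError):
    """Regression design matrix is singular (e.g. no variance in X)."""
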