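"""Exception hierarchy shared across the package."""


class RascoreError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RascoreError):
    """A required column is missing or the column mapping is invalid."""


class RowParseError(RascoreError):
    """A cell in a specific data row could not be parsed.

    Carries ``row_index`` (0-based data-row index, header excluded).
    """

    def __init__(self, message: str, row_index: int):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class DegenerateDataError(RascoreError):
    """Input data cannot support the requested computation
    (e.g. a single-class outcome for ROC analysis)."""


class SeparationError(RascoreError):
    """Complete or quasi-complete separation in a logistic fit.

    Carries ``term``, the offending model term.
    """

    def __init__(self, term: str):
        super().__init__(
            f"complete or quasi-complete separation detected for term {term!r}; "
            "the maximum-likelihood estimate does not exist"
        )
        self.term = term


class CollinearityError(RascoreError):
    """Rank-deficient design matrix."""


class ConfigurationError(RascoreError):
    """Invalid generator or pipeline configuration."""


class ScoringError(RascoreError):
    """A record lacks an indicator required by the scoring system, or
    coefficients are not risk-coded."""
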