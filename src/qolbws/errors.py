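"""Exception hierarchy for the qolbws pipeline."""

__all__ = [
    "QolBwsError",
    "SchemaError",
    "EmptyAnalysisError",
    "EmptySegmentationError",
    "DegenerateTableError",
    "InsufficientSupportError",
    "ConfigError",
]


class QolBwsError(Exception):
    """Base class for all qolbws errors."""


class SchemaError(QolBwsError):
    """A required column or demographic variable is missing or unknown."""


class EmptyAnalysisError(QolBwsError):
    """No valid records remain for analysis."""


class EmptySegmentationError(QolBwsError):
    """No demographic category reaches the segment size floor."""


class DegenerateTableError(QolBwsError):
    """A contingency table collapsed to a single row or column."""


class InsufficientSupportError(QolBwsError):
    """A persona selector matched fewer records than its minimum support."""

    def __init__(self, message: str, n_matched: int):
        super().__init__(message)
        self.n_matched = n_matched


class ConfigError(QolBwsError):
    """A simulation configuration failed validation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid simulation config: " + "; ".join(self.problems))
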