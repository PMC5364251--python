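"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid user input: malformed factors, tables, or datasets."""


class DegenerateFactorError(ValidationError):
    """A categorical factor with fewer than two observed levels."""


class ZeroCellError(ValidationError):
    """A cross-classification cell with zero observations where a
    weighted-effect interaction column needs a positive count."""


class RankDeficiencyError(ValidationError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()) -> None:
        super().__init__(message)
        self.columns = columns


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, iterations: int | None = None,
                 history: object = None) -> None:
        super().__init__(message)
        self.iterations = iterations
        self.history = history


class CompletionError(RuntimeError):
    """Refit-based and constraint-based omitted-category estimates disagree
    beyond tolerance, signalling an internal coding bug."""
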