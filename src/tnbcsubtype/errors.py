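"""Exception hierarchy for tnbcsubtype."""


class TnbcSubtypeError(Exception):
    """Base class for all package errors."""


class ParseError(TnbcSubtypeError):
    """A file could not be parsed (malformed header, non-numeric cell, empty file)."""


class ValidationError(TnbcSubtypeError):
    """An input violates a documented invariant (duplicate IDs, bad shapes, ...)."""


class CoverageError(ValidationError):
    """Too many signature genes are missing from an expression matrix.

    Carries the :class:`~tnbcsubtype.io.CoverageReport` that triggered the
    refusal so callers can inspect which genes were absent.
    """

    def __init__(self, report, max_missing: float):
        self.report = report
        self.max_missing = max_missing
        super().__init__(
            f"{report.missing_fraction:.1%} of signature genes are missing "
            f"(limit {max_missing:.0%}): classification refused"
        )
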