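"""Exception types shared across the package."""


class FamevolError(Exception):
    """Base class for package-specific failures."""


class SaturationError(FamevolError):
    """Raised when a distance correction is undefined (proportion >= 3/4)."""


class BacktranslationError(FamevolError):
    """Raised when a CDS does not translate to its claimed protein row."""

    def __init__(self, seq_id: str, position: int, message: str = ""):
        self.seq_id = seq_id
        self.position = position
        super().__init__(
            message or f"CDS/protein mismatch for {seq_id!r} at codon {position}"
        )


class GFFParseError(FamevolError):
    """Raised on malformed GFF3 input; carries the offending line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ConvergenceWarningError(FamevolError):
    """Raised only when a caller demands a converged fit and none was found."""
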