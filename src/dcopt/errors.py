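"""Exception hierarchy for library design."""


class LibraryDesignError(Exception):
    """Base class for all package errors."""


class CodonParseError(LibraryDesignError, ValueError):
    """A string is not a valid 3-letter IUPAC degenerate codon."""


class CountsTableError(LibraryDesignError, ValueError):
    """A counts table is malformed (bad symbol, duplicate row/column, non-integer cell)."""


class ConfigError(LibraryDesignError, ValueError):
    """A run configuration fails validation; the message names the offending field."""


class InfeasiblePositionError(LibraryDesignError):
    """No admissible codon set exists at a position under the given constraints."""

    def __init__(self, label: str, message: str | None = None):
        self.label = label
        super().__init__(message or f"position {label!r} is infeasible")


class InfeasibleLibraryError(LibraryDesignError):
    """No codon assignment satisfies the diversity and primer limits."""


class BudgetExceededError(LibraryDesignError):
    """A brute-force oracle would exceed its enumeration budget."""
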