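"""Exception hierarchy shared across the package."""


class PhenanomError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenanomError):
    """A configuration file or schema is invalid or incomplete."""


class DomainError(PhenanomError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class MissingDataError(PhenanomError):
    """A required observation (e.g. a climate month) is absent.

    The message always names the offending (series, year, month) or
    (year, variable) so alignment failures are actionable.
    """


class RowParseError(PhenanomError):
    """One or more input rows failed to parse; carries row-indexed details."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems[:20])
        more = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} malformed row(s): {lines}{more}")


class SingularFitError(DomainError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")
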