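"""Exception hierarchy shared across the package."""


class ChronopathError(Exception):
    """Base class for all package-specific errors."""


class WorldCorruptionError(ChronopathError):
    """A world-state invariant audit failed (superinfection, negative
    resources, orphaned genotype, abundance mismatch)."""


class EmptyWindowError(ChronopathError):
    """No living pathogen exists anywhere in the requested sampling window."""


class NoQualifyingNativesError(ChronopathError):
    """No native pathogen was at least as abundant as the invader, so the
    population-size-matched persistence comparison is undefined."""


class ConstantInputError(ChronopathError):
    """Rank correlation requested on a constant vector."""


class SchemaError(ChronopathError):
    """An on-disk table violated the expected schema."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
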