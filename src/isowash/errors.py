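"""Exception hierarchy shared across the package."""


class IsowashError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IsowashError, ValueError):
    """Invalid input value or parameter."""


class SchemaError(IsowashError):
    """A required column is missing from a tabular input."""


class DuplicateSampleError(IsowashError):
    """Two breath samples share the same (bird_id, time_min)."""


class RowParseError(IsowashError):
    """A numeric field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class DataAdequacyError(IsowashError):
    """One or more birds have too few samples to fit; lists offenders."""

    def __init__(self, bird_ids: list[str]):
        self.bird_ids = list(bird_ids)
        super().__init__(
            "birds with fewer than 2 samples cannot be fit: "
            + ", ".join(self.bird_ids)
        )


class InsufficientSamplesError(IsowashError):
    """Too few posterior draws for a summary operation."""


class EmptyGroupError(IsowashError):
    """A requested pooling group contains no birds."""


class DegenerateMixingError(IsowashError):
    """Mixing endpoints coincide; the proportion is undefined."""


class ContractError(IsowashError):
    """A state/parameter pairing contract was violated."""


class InsufficientDataError(IsowashError):
    """Too few trace points for segmented regression."""
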