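"""Exception hierarchy shared across the package."""


class FishspectraError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FishspectraError):
    """A table or run configuration is unusable (e.g. missing column)."""


class TableValidationError(FishspectraError):
    """One or more data rows violate a field constraint.

    Carries the offending 1-based line numbers so the file can be fixed.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class EmptyCommunityError(FishspectraError):
    """An operation that needs at least one individual received none."""


class MissingAttributesError(FishspectraError):
    """A catch record references a species absent from the attribute table."""

    def __init__(self, species: list[str]):
        super().__init__(
            "species without attribute rows: " + ", ".join(sorted(species))
        )
        self.species = species


class DegenerateInputError(FishspectraError):
    """Input is mathematically degenerate for the requested statistic
    (single species for evenness, constant column for z-score, ...)."""
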