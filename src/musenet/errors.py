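"""Exception hierarchy shared across the package."""


class MusenetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MusenetError):
    """Input columns do not match the expected instrument layout."""


class LikertRangeError(MusenetError):
    """An item response falls outside the admissible 1..5 range."""

    def __init__(self, respondent, item, value):
        self.respondent = respondent
        self.item = item
        self.value = value
        super().__init__(
            f"response {value!r} out of range 1..5 "
            f"(respondent {respondent!r}, item {item!r})"
        )


class DegenerateDataError(MusenetError):
    """Data are degenerate for the requested computation (e.g. zero variance)."""


class ConfigError(MusenetError):
    """Invalid generator or pipeline configuration."""


class EstimationError(MusenetError):
    """A network estimation step failed."""
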