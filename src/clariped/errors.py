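"""Exception hierarchy."""


class ClaripedError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(ClaripedError, ValueError):
    """A caller-supplied value violates a precondition."""


class TableConfigError(ClaripedError):
    """A score-band / policy configuration is malformed or non-covering."""


class CatalogError(ClaripedError):
    """A discriminator catalog is malformed."""


class IncompleteMeasurementError(ClaripedError):
    """A required vital sign is missing; the offending field is named."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing required vital sign: {field}")


class IncompleteEncounterError(ClaripedError):
    """A mandatory assessment field (pain, appearance) is missing."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing mandatory assessment field: {field}")


class DegenerateInputError(ClaripedError, ValueError):
    """A statistic is undefined for the supplied data."""


class SchemaError(ClaripedError):
    """An input file does not match the expected schema."""
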