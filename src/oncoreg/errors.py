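"""Exception hierarchy for the registry toolkit."""


class OncoregError(Exception):
    """Base class for all errors raised by this package."""


class OntologyFormatError(OncoregError):
    """The ontology file could not be parsed."""


class OntologySchemaError(OncoregError):
    """The ontology parses but is missing required structure."""


class UnknownEntityError(OncoregError, KeyError):
    """Lookup of a class, property or individual that is not declared."""

    def __str__(self) -> str:  # KeyError quotes its args; keep a plain message
        return Exception.__str__(self)


class ConfigError(OncoregError):
    """A configuration file is malformed or violates a constraint."""


class MappingError(OncoregError):
    """Mapping rules reference entities missing from the ontology."""


class ReferentialIntegrityError(OncoregError):
    """A foreign key in the registry does not resolve."""


class QueryValidationError(OncoregError):
    """A query model violates the ontology (domain/range/aggregation rules)."""


class DataError(OncoregError):
    """Individual-level data is inconsistent (e.g. diagnosis without a date)."""
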