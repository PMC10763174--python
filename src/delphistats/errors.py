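"""Exception hierarchy for panel-rating analysis."""


class DelphiError(Exception):
    """Base class for all delphistats errors."""


class SchemaError(DelphiError):
    """A required column is missing or cannot be resolved from the schema map."""


class ValidationError(DelphiError):
    """Input rows violate the rating-data contract (range, type, duplicates)."""


class EmptyPanelError(DelphiError):
    """An operation that needs at least one rating received none."""


class DomainError(DelphiError):
    """A numeric argument is outside its mathematical domain."""


class LinkageError(DelphiError):
    """Item lineage cannot be resolved (missing parent, cycle, bad relation)."""


class MappingError(DelphiError):
    """An item is missing from the category map."""


class ConfigError(DelphiError):
    """A simulation or classification configuration is invalid."""
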