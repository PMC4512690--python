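"""Exception hierarchy shared across the package."""


class ActiwinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActiwinError):
    """A raw input file violates its documented dialect (bad row width, empty file)."""


class SchemaError(ActiwinError):
    """A column mapping or feature-name contract is not satisfied."""


class AlignmentError(ActiwinError):
    """Instances or labels that must line up do not."""


class DomainError(ActiwinError, ValueError):
    """An operation was called outside its mathematical domain (empty series, single class)."""
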