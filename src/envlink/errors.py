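"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`EnvLinkError`
so callers (and the CLI) can catch one base class. Subclasses are named
after the contract they enforce, not after the module that raises them.
"""


class EnvLinkError(Exception):
    """Base class for all envlink errors."""


class FormatError(EnvLinkError):
    """Unsupported or unparseable file format (e.g. an .xlsx path)."""


class SchemaError(EnvLinkError):
    """A column/variable mapping names a column absent from the file."""


class GridError(EnvLinkError):
    """Grid axes are irregular, non-monotone, or inconsistent with values."""


class ValidationError(EnvLinkError):
    """A record violates a field-level contract (bad date, missing value)."""


class AmbiguityError(ValidationError):
    """An event row carries both a point and an area location."""


class GeometryError(EnvLinkError):
    """Invalid polygon: self-intersecting or zero-area."""


class NestingError(EnvLinkError):
    """Administrative-area parent links form a cycle."""


class UpliftError(EnvLinkError):
    """The semantic uplift references a geometry or entity it cannot find."""


class ConfigurationError(EnvLinkError):
    """A run configuration is incomplete or names an unknown key."""


class DisambiguationError(EnvLinkError):
    """Two datasets share a variable name and no rename map was given."""
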