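"""Exception hierarchy.

Every failure mode raised by this package derives from :class:`ClaridError`,
so callers (and the batch CLI) can catch one base class and still report a
meaningful error category per row.
"""


class ClaridError(Exception):
    """Base class for all errors raised by this package."""


class CodebookError(ClaridError):
    """The codebook document violates its structural contract."""


class ConfigurationError(ClaridError):
    """A configuration artifact (schema, mapping, codebook usage) is unusable."""


class VocabularyError(ClaridError):
    """A term or token is not part of the controlled vocabulary."""


class ConditionLookupError(ClaridError):
    """An ICD-10 code or rank is absent from the bundled lookup table."""


class DurationFormatError(ClaridError):
    """A duration token does not follow the restricted ISO 8601 grammar."""


class RangeError(ClaridError):
    """A numeric component is outside its encodable range."""


class StructureError(ClaridError):
    """An identifier string does not have the expected shape."""


class AmbiguityError(StructureError):
    """A stub admits more than one full parse (ill-chosen project stub codes)."""


class QRReadError(ClaridError):
    """An image does not contain a readable QR symbol."""
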