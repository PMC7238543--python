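"""Exception hierarchy for fcmkit.

All fcmkit-specific failures derive from :class:`FcmError` so callers can
catch the whole family; the leaves also derive from the matching builtin
(ValueError / RuntimeError / KeyError) so generic handling keeps working.
"""


class FcmError(Exception):
    """Base class for all fcmkit errors."""


class FormatError(FcmError, ValueError):
    """A file does not conform to the expected dialect (shape, labels)."""


class MapParseError(FormatError):
    """A cell, row or attribute could not be parsed into a weight/sign."""


class DuplicateEdgeError(FormatError):
    """The same ordered (source, target) pair appears more than once."""


class WeightRangeError(FormatError):
    """An edge weight is outside the allowed range for the map's state."""


class MapStateError(FcmError, RuntimeError):
    """An operation was applied to a map in the wrong scaled/unscaled state."""


class InvalidWalkError(FcmError, ValueError):
    """A walk references an edge that does not exist in the map."""


class MappingError(FcmError, ValueError):
    """A factor has no category (or an inconsistent one) in the mapping."""


class ScopeMismatchError(MapStateError):
    """Two category maps normalized over different scopes were compared."""
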