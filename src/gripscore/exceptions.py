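"""Exception hierarchy.

Everything derives from :class:`GripscoreError` so callers can catch the
package's failures in one clause; the concrete classes also subclass
``ValueError`` so plain defensive code keeps working.
"""


class GripscoreError(Exception):
    """Base class for all errors raised by gripscore."""


class InvalidParameterError(GripscoreError, ValueError):
    """A scalar argument is outside its allowed range."""


class InvalidDataError(GripscoreError, ValueError):
    """Data content violates an invariant (NaN, negative force, bad item score)."""


class ShapeMismatchError(GripscoreError, ValueError):
    """Paired arrays have incompatible lengths or grids."""


class ConsistencyError(GripscoreError, ValueError):
    """Records that must belong together (same subject/visit) do not."""


class DegenerateInputError(GripscoreError, ValueError):
    """Input leaves the statistic undefined (zero variance, constant x)."""


class FormatError(GripscoreError, ValueError):
    """A file does not match the expected on-disk format."""
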