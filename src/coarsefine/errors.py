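"""Exception hierarchy.

All errors derive from :class:`CoarseFineError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin so generic code keeps working.
"""


class CoarseFineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoarseFineError, ValueError):
    """Invalid layer/stack configuration (non-positive extents, bad variant)."""


class GeometryError(CoarseFineError, ValueError):
    """A sliding window does not fit the grid it is applied to."""


class ShapeError(CoarseFineError, ValueError):
    """Matrix operands with inconsistent shapes."""


class NumericError(CoarseFineError, FloatingPointError):
    """Non-finite values produced where finite ones are required."""
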