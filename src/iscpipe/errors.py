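"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`IscPipeError` so callers can catch the
package's failures with a single except clause while still letting
programming errors (TypeError etc.) propagate.
"""


class IscPipeError(Exception):
    """Base class for all iscpipe errors."""


class ParameterError(IscPipeError, ValueError):
    """An argument is outside its documented domain."""


class DataFormatError(IscPipeError, ValueError):
    """An input file or table violates its format contract."""


class GeometryError(IscPipeError, ValueError):
    """ROI/grid geometry is inconsistent (empty mask, grid mismatch...)."""


class ValidationError(IscPipeError, ValueError):
    """Input data violate an analysis precondition (range, shape, NaN...)."""


class DegenerateDataError(IscPipeError, ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""
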