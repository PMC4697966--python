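"""Exception hierarchy.

All package errors derive from :class:`HumeroMorphError` so callers can
catch everything from one base while still distinguishing format problems
(bad files) from validation problems (inconsistent data), geometric
construction failures and measurement failures.
"""


class HumeroMorphError(Exception):
    """Base class for all package errors."""


class FormatError(HumeroMorphError):
    """A file could not be parsed or has the wrong shape/columns."""


class ValidationError(HumeroMorphError):
    """Data is readable but violates a documented invariant."""


class GeometryError(HumeroMorphError):
    """A landmark or region construction failed."""


class MeasurementError(HumeroMorphError):
    """A morphometric operator could not produce a value."""


class ParameterError(HumeroMorphError):
    """A configuration parameter is outside its documented range."""


class InsufficientDataError(HumeroMorphError):
    """Too few observations for the requested statistical procedure."""


class SpecError(HumeroMorphError):
    """A synthetic-section specification is invalid or unreachable."""
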