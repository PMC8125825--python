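"""Exception hierarchy for manuclass.

All errors raised by the library derive from :class:`ManuclassError` so callers
can catch the package's failures with a single except clause.
"""


class ManuclassError(Exception):
    """Base class for all manuclass errors."""


class FormatError(ManuclassError):
    """A file does not match the documented CSV dialect (e.g. missing column)."""


class DataError(ManuclassError):
    """A file parses but its content violates an invariant (e.g. non-monotone time)."""


class SingularFitError(ManuclassError):
    """Calibration fit is underdetermined (fewer than two distinct reference values)."""


class LookupError_(ManuclassError):
    """Calibration coefficients missing for a requested sensor/axis."""


class EmptySegmentError(ManuclassError):
    """An annotated window contains no samples of the recording."""


class DegenerateLabelsError(ManuclassError):
    """A ROC analysis received labels with only one class present."""


class DegenerateFoldError(ManuclassError):
    """A cross-validation training split is missing a category."""
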