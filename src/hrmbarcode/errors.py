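"""Exception hierarchy for hrmbarcode.

All package-specific errors derive from :class:`HrmBarcodeError` so callers
can catch one base class at CLI boundaries.
"""


class HrmBarcodeError(Exception):
    """Base class for all hrmbarcode errors."""


class InputError(HrmBarcodeError):
    """Malformed or empty input data."""


class AlignmentError(InputError):
    """Sequences that should share an aligned length do not."""


class LabelingError(InputError):
    """A record could not be assigned a species label."""


class DesignError(HrmBarcodeError):
    """Design task invoked on input that cannot support it."""


class IdentityUndefinedError(HrmBarcodeError):
    """Pairwise identity requested with zero comparable columns."""


class GridMismatchError(HrmBarcodeError):
    """Two curves do not share a temperature grid."""


class NormalizationError(HrmBarcodeError):
    """Melt-curve normalization failed (degenerate baselines)."""


class ModelError(HrmBarcodeError):
    """Inconsistent simulation model specification."""
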