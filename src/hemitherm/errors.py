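"""Exception hierarchy.

Every hemitherm error derives from :class:`HemithermError` so callers can
catch the whole family; the CLI maps each class to a distinct exit code
(see :mod:`hemitherm.cli`).
"""


class HemithermError(Exception):
    """Base class for all hemitherm errors."""


class GridFormatError(HemithermError):
    """A temperature-grid or raster file does not parse (ragged rows, bad
    tokens, wrong channel count)."""


class TemperatureBandError(HemithermError):
    """A non-masked temperature lies outside the plausibility band, or no
    plausible pixel remains after masking."""


class CalibrationError(HemithermError):
    """Invalid radiometric calibration (e.g. zero gain)."""


class RoiBoundsError(HemithermError):
    """An ROI, hemiface split, or hotspot ellipse does not fit inside its
    frame."""


class DimensionMismatchError(HemithermError):
    """Two matrices or masks that must share a shape do not."""


class MatrixKindError(HemithermError):
    """An operation received a temperature matrix of the wrong kind (e.g.
    thresholding a non-differential matrix)."""


class ThresholdError(HemithermError):
    """Non-positive or otherwise invalid ΔT threshold."""


class GradeError(HemithermError):
    """Unrecognized clinical severity grade."""


class EmptyDataError(HemithermError):
    """All pixels invalid: no data to summarize or render."""


class PlacementError(HemithermError):
    """A region pixel cannot be placed back onto the full frame."""


class PhantomSpecError(HemithermError):
    """Invalid synthetic-phantom specification."""


class ComparabilityError(HemithermError):
    """Two analysis reports cannot be compared (ROI geometry or threshold
    policy differ)."""
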