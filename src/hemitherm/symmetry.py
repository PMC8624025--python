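"""Bilateral symmetry differential mapping.

The core procedure: extract equally sized rectangular ROIs from the healthy
and diseased hemifaces, mirror the healthy matrix about its vertical axis so
contralateral pixels correspond, subtract to obtain the differential map

    R[i, j] = D[i, j] − H*[i, j],      H*[i, j] = H[i, n−1−j],

and zero every differential below a severity-dependent cut-off ΔT_threshold
(values exactly equal to the cut-off survive).  In a healthy face the two
hemifaces are thermally near-symmetric, so R fluctuates around zero;
inflammation appears as a connected patch of large positive ΔT.

Indices are 0-based, row-major, origin top-left, ranges half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import (
    DimensionMismatchError,
    EmptyDataError,
    MatrixKindError,
    RoiBoundsError,
    ThresholdError,
)
from .io import ThermalFrame


class MatrixKind(enum.Enum):
    """Role of a temperature matrix in the differential procedure."""

    HEALTHY = "healthy"
    MIRRORED_HEALTHY = "mirrored-healthy"
    DISEASED = "diseased"
    DIFFERENTIAL = "differential"
    THRESHOLDED = "thresholded"


@dataclass(eq=False)
class TemperatureMatrix:
    """An m×n ROI extract, in °C (or °C-difference for result matrices)."""

    values: np.ndarray
    kind: MatrixKind

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DimensionMismatchError(
                f"temperature matrix must be 2-D with positive size, got {arr.shape}"
            )
        self.values = arr
        self.kind = MatrixKind(self.kind)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in frame pixel coordinates.

    ``top``/``left`` are inclusive 0-based indices; the ROI spans rows
    ``[top, top+height)`` and columns ``[left, left+width)``.  ``laterality``
    records which hemiface the ROI covers ('left' or 'right'); it is
    descriptive metadata and does not alter the arithmetic.
    """

    top: int
    left: int
    height: int
    width: int
    laterality: str = "left"
    label: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise RoiBoundsError(
                f"ROI must have positive area, got {self.height}×{self.width}"
            )
        if self.top < 0 or self.left < 0:
            raise RoiBoundsError(
                f"ROI origin must be non-negative, got top={self.top}, left={self.left}"
            )
        if self.laterality not in ("left", "right"):
            raise RoiBoundsError(
                f"laterality must be 'left' or 'right', got {self.laterality!r}"
            )


@dataclass(frozen=True)
class ThresholdPolicy:
    """Severity cut-off ΔT_threshold (°C) and where it came from."""

    delta_t_threshold: float
    source: str = "explicit"  # 'explicit' or 'severity-grade'
    grade: str | None = None

    def __post_init__(self) -> None:
        if not (self.delta_t_threshold > 0):
            raise ThresholdError(
                f"ΔT threshold must be positive, got {self.delta_t_threshold}"
            )


def extract_roi(frame: ThermalFrame, roi: ROISpec, kind: MatrixKind) -> TemperatureMatrix:
    """Extract ``roi`` from ``frame`` as an m×n matrix of the given kind.

    ``result[i, j] = frame.temps[roi.top + i, roi.left + j]``.
    """
    over_r = roi.top + roi.height - frame.height
    over_c = roi.left + roi.width - frame.width
    if over_r > 0 or over_c > 0:
        raise RoiBoundsError(
            f"ROI {roi.height}×{roi.width} at (top={roi.top}, left={roi.left}) "
            f"overhangs {frame.height}×{frame.width} frame by "
            f"{max(over_r, 0)} row(s) and {max(over_c, 0)} column(s)"
        )
    block = frame.temps[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width]
    return TemperatureMatrix(block.copy(), MatrixKind(kind))


def mirror_matrix(M: TemperatureMatrix) -> TemperatureMatrix:
    """Mirror about the vertical axis: ``out[i, j] = M[i, n−1−j]``.

    Healthy matrices become mirrored-healthy and vice versa (the transform is
    an involution); other kinds keep their kind.
    """
    flip = {
        MatrixKind.HEALTHY: MatrixKind.MIRRORED_HEALTHY,
        MatrixKind.MIRRORED_HEALTHY: MatrixKind.HEALTHY,
    }
    kind = flip.get(M.kind, M.kind)
    return TemperatureMatrix(M.values[:, ::-1].copy(), kind)


def differential_map(D: TemperatureMatrix, H: TemperatureMatrix) -> TemperatureMatrix:
    """Pixel-wise differential ``R = D − mirror(H)``.

    ``D`` must be the diseased matrix and ``H`` the (un-mirrored) healthy
    matrix of identical dimensions.  Invalid pixels in either operand
    propagate as invalid.
    """
    if D.kind is not MatrixKind.DISEASED:
        raise MatrixKindError(f"D must have kind 'diseased', got {D.kind.value!r}")
    if H.kind is not MatrixKind.HEALTHY:
        raise MatrixKindError(f"H must have kind 'healthy', got {H.kind.value!r}")
    if D.shape != H.shape:
        raise DimensionMismatchError(
            f"diseased matrix is {D.m}×{D.n} but healthy matrix is {H.m}×{H.n}; "
            "paired ROIs must have identical dimensions"
        )
    Hstar = mirror_matrix(H)
    return TemperatureMatrix(D.values - Hstar.values, MatrixKind.DIFFERENTIAL)


def threshold_map(R: TemperatureMatrix, policy: ThresholdPolicy) -> TemperatureMatrix:
    """Zero every differential strictly below ``policy.delta_t_threshold``.

    Values exactly equal to the cut-off survive; negative differentials are
    always zeroed (the cut-off is positive).  Invalid pixels stay invalid.
    """
    if R.kind is not MatrixKind.DIFFERENTIAL:
        raise MatrixKindError(
            f"thresholding applies to a differential matrix, got {R.kind.value!r}"
        )
    thr = policy.delta_t_threshold
    out = np.where(R.values >= thr, R.values, 0.0)
    out[~np.isfinite(R.values)] = np.nan
    return TemperatureMatrix(out, MatrixKind.THRESHOLDED)


def split_hemifaces(
    frame: ThermalFrame,
    axis_col: int,
    roi_height: int,
    roi_width: int,
    top: int | None = None,
    diseased_side: str = "left",
) -> tuple[TemperatureMatrix, TemperatureMatrix]:
    """Extract two contralateral ROIs from a single frontal frame.

    ``axis_col`` is the sagittal-midline column index, read as the boundary
    between columns ``axis_col−1`` and ``axis_col``: the left ROI spans
    columns ``[axis_col − roi_width, axis_col)`` and the right ROI
    ``[axis_col, axis_col + roi_width)``.  Rows span ``[top, top+roi_height)``
    (vertically centred when ``top`` is None).  Returns
    ``(diseased, healthy)`` per ``diseased_side``.
    """
    if diseased_side not in ("left", "right"):
        raise RoiBoundsError(f"diseased_side must be 'left' or 'right', got {diseased_side!r}")
    if top is None:
        top = max(0, (frame.height - roi_height) // 2)
    left_origin = axis_col - roi_width
    if left_origin < 0:
        raise RoiBoundsError(
            f"left hemiface ROI of width {roi_width} overhangs the frame: "
            f"columns [{left_origin}, {axis_col}) with axis_col={axis_col}"
        )
    if axis_col + roi_width > frame.width:
        raise RoiBoundsError(
            f"right hemiface ROI of width {roi_width} overhangs the frame: "
            f"columns [{axis_col}, {axis_col + roi_width}) in a "
            f"{frame.width}-column frame"
        )
    roi_left = ROISpec(top, left_origin, roi_height, roi_width, laterality="left")
    roi_right = ROISpec(top, axis_col, roi_height, roi_width, laterality="right")
    if diseased_side == "left":
        d = extract_roi(frame, roi_left, MatrixKind.DISEASED)
        h = extract_roi(frame, roi_right, MatrixKind.HEALTHY)
    else:
        d = extract_roi(frame, roi_right, MatrixKind.DISEASED)
        h = extract_roi(frame, roi_left, MatrixKind.HEALTHY)
    return d, h


def hemiface_rois(
    frame: ThermalFrame,
    axis_col: int,
    roi_height: int,
    roi_width: int,
    top: int | None = None,
) -> tuple[ROISpec, ROISpec]:
    """The (left, right) ROI specs that :func:`split_hemifaces` would use."""
    if top is None:
        top = max(0, (frame.height - roi_height) // 2)
    return (
        ROISpec(top, axis_col - roi_width, roi_height, roi_width, laterality="left"),
        ROISpec(top, axis_col, roi_height, roi_width, laterality="right"),
    )


def asymmetry_summary(
    R: TemperatureMatrix,
    thresholds: tuple[float, ...] = (2.0, 3.0),
) -> dict:
    """Summary statistics of a differential (or thresholded) map.

    Returns max ΔT, mean ΔT over valid pixels, the valid-pixel count, and for
    each requested threshold the count and fraction of valid pixels with
    ΔT ≥ threshold.
    """
    if R.kind not in (MatrixKind.DIFFERENTIAL, MatrixKind.THRESHOLDED):
        raise MatrixKindError(
            f"asymmetry summary applies to differential/thresholded matrices, "
            f"got {R.kind.value!r}"
        )
    valid = R.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise EmptyDataError("all pixels invalid: nothing to summarize")
    vals = R.values[valid]
    counts = {float(t): int((vals >= t).sum()) for t in thresholds}
    return {
        "max_delta_t_C": float(vals.max()),
        "mean_delta_t_C": float(vals.mean()),
        "n_valid": n_valid,
        "n_total": int(R.values.size),
        "counts_ge": counts,
        "fractions_ge": {t: c / n_valid for t, c in counts.items()},
    }
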