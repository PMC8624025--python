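"""Hotspot segmentation and severity-grade threshold mapping.

A thresholded differential map is converted into labeled inflammation
regions: the connected components of the suprathreshold pixel set, each with
area, temperature and shape descriptors.  The largest region is interpreted
as the main active site of inflammation.

Clinical severity grades map to published ΔT cut-offs: *severe* → 3.0 °C,
*moderate* → 2.0 °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionMismatchError, GradeError, MatrixKindError
from .symmetry import MatrixKind, TemperatureMatrix, ThresholdPolicy

#: Published severity-grade → ΔT cut-off mapping, °C.
GRADE_THRESHOLDS: dict[str, float] = {"severe": 3.0, "moderate": 2.0}


def threshold_for_grade(grade: str) -> ThresholdPolicy:
    """Map a clinical severity grade to its ΔT cut-off.

    ``severe`` → 3.0 °C, ``moderate`` → 2.0 °C (case-insensitive).
    """
    key = str(grade).strip().lower()
    if key not in GRADE_THRESHOLDS:
        raise GradeError(
            f"unknown severity grade {grade!r}; valid grades: "
            + ", ".join(sorted(GRADE_THRESHOLDS))
        )
    return ThresholdPolicy(GRADE_THRESHOLDS[key], source="severity-grade", grade=key)


@dataclass(frozen=True)
class HotspotRegion:
    """One connected suprathreshold component with descriptors.

    ``pixels`` are (row, col) coordinates local to the ROI.  ``elongation``
    is the square-root ratio of the principal second moments of the pixel
    set (pixels treated as unit squares, so a single pixel has elongation
    1.0); it is ≥ 1 and grows with how stretched the region is.
    """

    label: int
    pixels: frozenset[tuple[int, int]]
    area: int
    max_delta_t: float
    mean_delta_t: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (top, left, height, width)
    elongation: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this region on a grid of the given shape."""
        out = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        out[list(rows), list(cols)] = True
        return out


def _elongation(coords: np.ndarray) -> float:
    # second central moments of the pixel set, each pixel a unit square
    # (adds 1/12 per axis, keeping single pixels and lines non-degenerate)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords) + np.eye(2) / 12.0
    lo, hi = np.linalg.eigvalsh(cov)
    return float(math.sqrt(hi / lo))


def segment_hotspots(
    Rp: TemperatureMatrix,
    connectivity: int = 8,
    min_region_area: int = 5,
) -> list[HotspotRegion]:
    """Label the connected components of the suprathreshold pixel set.

    Components smaller than ``min_region_area`` pixels are discarded
    (``min_region_area=0`` disables despeckling).  Regions are returned in
    descending area order, ties broken by higher max ΔT then by top-left-most
    centroid, and relabeled 1..k in that order; the first region is the main
    inflammation site.
    """
    if Rp.kind is not MatrixKind.THRESHOLDED:
        raise MatrixKindError(
            f"segmentation applies to a thresholded matrix, got {Rp.kind.value!r}"
        )
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    mask = np.isfinite(Rp.values) & (Rp.values > 0)
    labeled, n_labels = ndimage.label(mask, structure=structure)

    regions: list[HotspotRegion] = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labeled == lab)
        area = len(coords)
        if area < min_region_area:
            continue
        vals = Rp.values[coords[:, 0], coords[:, 1]]
        centroid = coords.mean(axis=0)
        top, left = coords.min(axis=0)
        bot, right = coords.max(axis=0)
        regions.append(
            HotspotRegion(
                label=0,  # assigned after sorting
                pixels=frozenset((int(r), int(c)) for r, c in coords),
                area=area,
                max_delta_t=float(vals.max()),
                mean_delta_t=float(vals.mean()),
                centroid=(float(centroid[0]), float(centroid[1])),
                bbox=(int(top), int(left), int(bot - top + 1), int(right - left + 1)),
                elongation=_elongation(coords.astype(float)),
            )
        )

    regions.sort(
        key=lambda r: (-r.area, -r.max_delta_t, r.centroid[0], r.centroid[1])
    )
    return [
        HotspotRegion(
            label=i + 1,
            pixels=r.pixels,
            area=r.area,
            max_delta_t=r.max_delta_t,
            mean_delta_t=r.mean_delta_t,
            centroid=r.centroid,
            bbox=r.bbox,
            elongation=r.elongation,
        )
        for i, r in enumerate(regions)
    ]


def label_image(regions: list[HotspotRegion], shape: tuple[int, int]) -> np.ndarray:
    """8-bit label image (0 = background) from a sorted region list."""
    out = np.zeros(shape, dtype=np.uint8)
    for r in regions:
        rows, cols = zip(*r.pixels)
        out[list(rows), list(cols)] = min(r.label, 255)
    return out


@dataclass(frozen=True)
class RecoveryScore:
    """Overlap between a detected mask and a ground-truth mask."""

    dice: float
    jaccard: float
    centroid_distance_px: float


def evaluate_recovery(detected: np.ndarray, truth: np.ndarray) -> RecoveryScore:
    """Dice, Jaccard and centroid distance between two boolean masks.

    Dice = 2|A∩B| / (|A|+|B|); both masks empty counts as perfect agreement
    (Dice = Jaccard = 1, distance 0).  The centroid distance is NaN when
    exactly one mask is empty.
    """
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise DimensionMismatchError(
            f"mask shapes differ: {detected.shape} vs {truth.shape}"
        )
    na, nb = int(detected.sum()), int(truth.sum())
    if na == 0 and nb == 0:
        return RecoveryScore(1.0, 1.0, 0.0)
    inter = int((detected & truth).sum())
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    jaccard = inter / union
    if na == 0 or nb == 0:
        dist = float("nan")
    else:
        ca = np.argwhere(detected).mean(axis=0)
        cb = np.argwhere(truth).mean(axis=0)
        dist = float(np.hypot(*(ca - cb)))
    return RecoveryScore(float(dice), float(jaccard), dist)
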