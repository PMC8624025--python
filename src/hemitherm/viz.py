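"""Frame-coordinate repositioning and rendering.

Detected regions live in ROI-local coordinates; :func:`map_region_to_frame`
repositions them onto the full face so the inflammation site can be shown in
its anatomical location.  Rendering is done at native raster resolution
(colormapped RGB written with Pillow) so outputs are deterministic and
pixel-exact; the 3-D surface view goes through matplotlib.

The default palette is perceptually uniform ("inferno"); the classic rainbow
look of clinical thermography software is available via ``cmap="rainbow"``
or ``"jet"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import EmptyDataError, PlacementError
from .hotspots import HotspotRegion
from .io import ThermalFrame
from .symmetry import ROISpec, TemperatureMatrix

PixelSet = frozenset  # of (row, col)


@dataclass(frozen=True)
class FramePlacement:
    """How ROI-local coordinates map back into the full frame.

    ``mirrored=True`` means the region was detected in mirrored orientation
    (e.g. on the mirrored-healthy matrix) and must be un-mirrored about the
    ROI's vertical axis before placement.
    """

    roi: ROISpec
    mirrored: bool = False


def map_region_to_frame(
    region: HotspotRegion | frozenset | set,
    placement: FramePlacement,
    frame_shape: tuple[int, int] | None = None,
) -> frozenset:
    """Reposition ROI-local (row, col) pixels into frame coordinates.

    ``(i, j) → (top+i, left+j)``, or ``(top+i, left+(n−1−j))`` when mirrored.
    The mapping is a bijection on the region.  If ``frame_shape`` is given,
    any mapped pixel outside it raises :class:`PlacementError`.
    """
    pixels = region.pixels if isinstance(region, HotspotRegion) else region
    roi = placement.roi
    out = set()
    for i, j in pixels:
        if not (0 <= i < roi.height and 0 <= j < roi.width):
            raise PlacementError(
                f"region pixel ({i}, {j}) lies outside the {roi.height}×{roi.width} ROI"
            )
        jj = roi.width - 1 - j if placement.mirrored else j
        p = (roi.top + i, roi.left + jj)
        if frame_shape is not None and not (
            0 <= p[0] < frame_shape[0] and 0 <= p[1] < frame_shape[1]
        ):
            raise PlacementError(
                f"mapped pixel {p} falls outside the {frame_shape} frame"
            )
        out.add(p)
    return frozenset(out)


def map_frame_to_region(pixels: frozenset | set, placement: FramePlacement) -> frozenset:
    """Inverse of :func:`map_region_to_frame`."""
    roi = placement.roi
    out = set()
    for r, c in pixels:
        i, jj = r - roi.top, c - roi.left
        if not (0 <= i < roi.height and 0 <= jj < roi.width):
            raise PlacementError(
                f"frame pixel ({r}, {c}) lies outside ROI at "
                f"(top={roi.top}, left={roi.left})"
            )
        j = roi.width - 1 - jj if placement.mirrored else jj
        out.add((i, j))
    return frozenset(out)


def _colorize(values: np.ndarray, cmap: str, vmin=None, vmax=None) -> np.ndarray:
    """Map a 2-D float array to uint8 RGB; invalid pixels render mid-gray."""
    from matplotlib import colormaps

    finite = np.isfinite(values)
    if not finite.any():
        raise EmptyDataError("all pixels invalid: nothing to render")
    lo = float(np.nanmin(values)) if vmin is None else vmin
    hi = float(np.nanmax(values)) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((values - lo) / span, 0.0, 1.0)
    norm[~finite] = 0.0
    rgba = colormaps[cmap](norm)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~finite] = 128
    return rgb


def _pixelset_to_mask(pixels, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if pixels:
        rows, cols = zip(*pixels)
        mask[list(rows), list(cols)] = True
    return mask


def render_overlay(
    base: ThermalFrame | np.ndarray,
    mask_pixels,
    path: str | Path,
    style: str = "contour",
    cmap: str = "inferno",
    color: tuple[int, int, int] = (0, 255, 255),
    alpha: float = 0.5,
    contour_width: int = 1,
) -> Path:
    """Render ``base`` with the detected region outlined or filled.

    ``style="contour"`` draws a 1-pixel (or wider) outline just outside the
    mask; pixels beyond the dilated contour are untouched.  ``style="fill"``
    alpha-blends ``color`` over the mask.  An empty mask renders the base
    with a warning banner instead of raising.  Output is a PNG whose bytes
    are deterministic for fixed inputs.
    """
    from PIL import Image, ImageDraw

    temps = base.temps if isinstance(base, ThermalFrame) else np.asarray(base, float)
    rgb = _colorize(temps, cmap)
    mask = _pixelset_to_mask(mask_pixels, temps.shape)
    if mask.any():
        if style == "contour":
            dilated = ndimage.binary_dilation(mask, iterations=max(1, contour_width))
            contour = dilated & ~mask
            rgb[contour] = color
        elif style == "fill":
            blended = (1 - alpha) * rgb[mask] + alpha * np.array(color, float)
            rgb[mask] = blended.round().astype(np.uint8)
        else:
            raise ValueError(f"style must be 'contour' or 'fill', got {style!r}")
        img = Image.fromarray(rgb)
    else:
        img = Image.fromarray(rgb)
        draw = ImageDraw.Draw(img)
        draw.text((4, 4), "no suprathreshold focus", fill=(255, 255, 255))
    path = Path(path)
    img.save(path, format="PNG")
    return path


def render_surface(
    M: TemperatureMatrix | np.ndarray,
    path: str | Path,
    cmap: str = "inferno",
    title: str | None = None,
) -> Path:
    """3-D surface plot of temperature (or ΔT) over (row, col).

    Large matrices are strided down to ≤ ~150 points per axis for a readable,
    fast render; axis ranges cover the data extent.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    values = M.values if isinstance(M, TemperatureMatrix) else np.asarray(M, float)
    if not np.isfinite(values).any():
        raise EmptyDataError("all pixels invalid: nothing to render")
    m, n = values.shape
    sr, sc = max(1, m // 150), max(1, n // 150)
    z = values[::sr, ::sc]
    rows = np.arange(0, m, sr)
    cols = np.arange(0, n, sc)
    cgrid, rgrid = np.meshgrid(cols, rows)

    fig = Figure(figsize=(7, 5), dpi=100)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(cgrid, rgrid, z, cmap=cmap, linewidth=0, antialiased=False)
    ax.set_xlabel("column (px)")
    ax.set_ylabel("row (px)")
    ax.set_zlabel("ΔT (°C)" if np.nanmin(values) < 10 else "T (°C)")
    if title:
        ax.set_title(title)
    ax.invert_yaxis()  # row 0 at the top, matching image orientation
    path = Path(path)
    fig.savefig(path, format="png", metadata={"Software": None})
    return path


def save_label_png(labels: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit label image (0 = background) as PNG."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path, format="PNG")
    return path
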