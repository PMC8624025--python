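"""Reading, validating and writing calibrated skin-temperature rasters.

The interchange format is a plain text grid of temperatures in °C, one image
row per line, with an optional YAML sidecar (``<file>.meta.yaml``) carrying
acquisition metadata (emissivity, capture time, subject id).  Raw 16-bit
radiometric rasters (TIFF/PNG) are supported through an affine digital-number
→ °C calibration.

Conventions
-----------
* Pixel ``[0, 0]`` is the top-left corner; arrays are row-major.
* Temperatures are stored already calibrated in °C.  Emissivity is carried as
  metadata only (thermal cameras apply it internally when exporting skin
  temperatures); no radiometric correction is performed here.
* Invalid / dead pixels are represented as NaN and are excluded from every
  downstream statistic.
* Finite temperatures must lie within a plausibility band, by default
  [15, 45] °C — facial skin plus generous fever/ambient margins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    CalibrationError,
    GridFormatError,
    TemperatureBandError,
)

#: Default plausibility band for facial skin temperature, °C.
DEFAULT_BAND: tuple[float, float] = (15.0, 45.0)

#: Emissivity of human skin; applied by the camera, recorded as metadata.
DEFAULT_EMISSIVITY: float = 0.98


@dataclass(eq=False)
class ThermalFrame:
    """A calibrated full-face (or hemiface) temperature raster.

    Parameters
    ----------
    temps
        2-D array of skin temperatures in °C.  NaN marks invalid pixels.
    emissivity
        Dimensionless emissivity used at acquisition, in (0, 1].
    capture_time, subject_id
        Optional acquisition metadata.
    band
        Plausibility band ``(lo, hi)`` in °C; any finite temperature outside
        it raises :class:`TemperatureBandError`.
    """

    temps: np.ndarray
    emissivity: float = DEFAULT_EMISSIVITY
    capture_time: str | None = None
    subject_id: str | None = None
    band: tuple[float, float] = DEFAULT_BAND

    units_note = "°C"

    def __post_init__(self) -> None:
        arr = np.asarray(self.temps, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise GridFormatError(
                f"temperature raster must be 2-D with positive size, got shape {arr.shape}"
            )
        if not (0.0 < float(self.emissivity) <= 1.0):
            raise TemperatureBandError(
                f"emissivity must lie in (0, 1], got {self.emissivity}"
            )
        lo, hi = self.band
        finite = np.isfinite(arr)
        bad = finite & ((arr < lo) | (arr > hi))
        if bad.any():
            rows, cols = np.nonzero(bad)
            offenders = ", ".join(
                f"{arr[r, c]:g} °C at ({r}, {c})"
                for r, c in list(zip(rows, cols))[:5]
            )
            more = "" if bad.sum() <= 5 else f" (+{int(bad.sum()) - 5} more)"
            raise TemperatureBandError(
                f"{int(bad.sum())} temperature(s) outside band [{lo}, {hi}] °C: "
                f"{offenders}{more}"
            )
        self.temps = arr

    @property
    def height(self) -> int:
        return self.temps.shape[0]

    @property
    def width(self) -> int:
        return self.temps.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of valid (finite) pixels."""
        return np.isfinite(self.temps)


@dataclass(frozen=True)
class RadiometricCalibration:
    """Affine digital-number → temperature conversion: ``T = gain·DN + offset``.

    ``invalid_value`` is an optional sentinel digital number marking dead
    pixels; matching pixels become NaN in the resulting frame.
    """

    gain: float
    offset: float
    invalid_value: int | None = None

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise CalibrationError("calibration gain must be nonzero")


@dataclass(frozen=True)
class GridDialect:
    """Text-grid dialect: field delimiter and decimal mark.

    European thermography software commonly exports decimal-comma CSVs with a
    semicolon delimiter; both styles are supported.  A comma cannot serve as
    both delimiter and decimal mark.
    """

    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.decimal not in (".", ","):
            raise GridFormatError(f"decimal mark must be '.' or ',', got {self.decimal!r}")
        if self.decimal == "," and self.delimiter == ",":
            raise GridFormatError(
                "decimal-comma mode requires a non-comma delimiter (use ';' or tab)"
            )


_SIDECAR_KEYS = ("emissivity", "capture_time", "subject_id")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def _read_sidecar(path: Path) -> dict:
    sp = _sidecar_path(path)
    if not sp.exists():
        return {}
    with open(sp) as fh:
        raw = yaml.safe_load(fh) or {}
    return {k: raw[k] for k in _SIDECAR_KEYS if k in raw and raw[k] is not None}


def read_temperature_grid(
    path: str | Path,
    dialect: GridDialect | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ThermalFrame:
    """Read a plain-text temperature grid into a validated :class:`ThermalFrame`.

    One image row per line; ``nan`` (any case) marks invalid pixels.  Metadata
    is taken from the ``<file>.meta.yaml`` sidecar when present, otherwise
    defaults apply (emissivity 0.98).

    Raises
    ------
    GridFormatError
        On ragged rows (names the first offending row) or unparseable tokens
        (names row and column).
    TemperatureBandError
        If any finite value falls outside ``band``.
    """
    dialect = dialect or GridDialect()
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise GridFormatError(f"{path}: empty grid file")

    width: int | None = None
    rows: list[list[float]] = []
    for r, line in enumerate(lines):
        tokens = line.split(dialect.delimiter)
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise GridFormatError(
                f"{path}: ragged row {r}: expected {width} fields, found {len(tokens)}"
            )
        vals = []
        for c, tok in enumerate(tokens):
            t = tok.strip()
            if dialect.decimal == ",":
                t = t.replace(",", ".")
            try:
                vals.append(float(t))
            except ValueError:
                raise GridFormatError(
                    f"{path}: unparseable token {tok.strip()!r} at row {r}, column {c}"
                ) from None
        rows.append(vals)

    temps = np.array(rows, dtype=float)
    meta = _read_sidecar(path)
    return ThermalFrame(temps, band=band, **meta)


def _format_value(v: float, decimal: str) -> str:
    if not np.isfinite(v):
        return "nan"
    s = repr(float(v))  # shortest exact round-trip representation
    if decimal == ",":
        s = s.replace(".", ",")
    return s


def write_temperature_grid(
    frame: ThermalFrame,
    path: str | Path,
    dialect: GridDialect | None = None,
) -> None:
    """Write ``frame`` as a text grid; exact round-trip with the reader.

    Values are written with Python's shortest-exact float representation, so
    ``read_temperature_grid(write_temperature_grid(f))`` reproduces the
    temperatures bit-for-bit.  A metadata sidecar is written whenever any
    metadata field differs from its default.
    """
    dialect = dialect or GridDialect()
    path = Path(path)
    with open(path, "w") as fh:
        for row in frame.temps:
            fh.write(dialect.delimiter.join(_format_value(v, dialect.decimal) for v in row))
            fh.write("\n")

    meta = {
        "emissivity": float(frame.emissivity),
        "capture_time": frame.capture_time,
        "subject_id": frame.subject_id,
    }
    nondefault = (
        frame.emissivity != DEFAULT_EMISSIVITY
        or frame.capture_time is not None
        or frame.subject_id is not None
    )
    sp = _sidecar_path(path)
    if nondefault:
        with open(sp, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
    elif sp.exists():
        sp.unlink()


def read_radiometric_image(
    path: str | Path,
    calib: RadiometricCalibration,
    band: tuple[float, float] = DEFAULT_BAND,
    **frame_meta,
) -> ThermalFrame:
    """Read a single-channel 16-bit (or any integer) raster and calibrate it.

    ``T[i, j] = gain · DN[i, j] + offset``.  Pixels equal to
    ``calib.invalid_value`` become NaN, as do calibrated temperatures falling
    outside ``band`` (treated as sensor artefacts rather than hard errors).

    Raises
    ------
    GridFormatError
        If the raster is multi-channel or not integer-typed.
    TemperatureBandError
        If no in-band pixel remains after masking.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        dn = np.asarray(tifffile.imread(path))
    else:
        from PIL import Image

        with Image.open(path) as img:
            dn = np.asarray(img)
    if dn.ndim != 2:
        raise GridFormatError(
            f"{path}: expected a single-channel raster, got shape {dn.shape}"
        )
    if not np.issubdtype(dn.dtype, np.integer):
        raise GridFormatError(f"{path}: expected an integer raster, got dtype {dn.dtype}")

    temps = calib.gain * dn.astype(float) + calib.offset
    if calib.invalid_value is not None:
        temps[dn == calib.invalid_value] = np.nan
    lo, hi = band
    temps[np.isfinite(temps) & ((temps < lo) | (temps > hi))] = np.nan
    if not np.isfinite(temps).any():
        raise TemperatureBandError(
            f"{path}: all calibrated temperatures fall outside band [{lo}, {hi}] °C"
        )
    return ThermalFrame(temps, band=band, **frame_meta)


def frame_metadata(frame: ThermalFrame) -> dict:
    """Serializable metadata dict for a frame (used by reports and sidecars)."""
    return {
        "height": frame.height,
        "width": frame.width,
        "emissivity": float(frame.emissivity),
        "capture_time": frame.capture_time,
        "subject_id": frame.subject_id,
        "units": ThermalFrame.units_note,
    }
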