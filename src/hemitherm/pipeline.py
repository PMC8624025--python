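"""End-to-end case analysis and longitudinal session comparison.

``analyze_case`` runs the full chain — extract ROIs, mirror, subtract,
threshold, segment, reposition, render — and returns an
:class:`AnalysisReport` that records every parameter affecting the output,
so a report fully determines a re-run.  ``compare_sessions`` compares two
reports of the same geometry/threshold (e.g. admission vs 48 h control) and
labels the evolution descriptively (stable / regressing / progressing).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ComparabilityError
from .hotspots import HotspotRegion, label_image, segment_hotspots
from .io import ThermalFrame, frame_metadata, read_temperature_grid
from .symmetry import (
    MatrixKind,
    ROISpec,
    TemperatureMatrix,
    ThresholdPolicy,
    asymmetry_summary,
    differential_map,
    extract_roi,
    split_hemifaces,
    hemiface_rois,
    threshold_map,
)
from .viz import FramePlacement, map_region_to_frame, render_overlay, render_surface, save_label_png

REPORT_SCHEMA_VERSION = 1


def _region_record(r: HotspotRegion) -> dict:
    return {
        "label": r.label,
        "area_px": r.area,
        "max_delta_t_C": r.max_delta_t,
        "mean_delta_t_C": r.mean_delta_t,
        "centroid_row": r.centroid[0],
        "centroid_col": r.centroid[1],
        "bbox_top": r.bbox[0],
        "bbox_left": r.bbox[1],
        "bbox_height": r.bbox[2],
        "bbox_width": r.bbox[3],
        "elongation": r.elongation,
    }


@dataclass
class AnalysisReport:
    """Complete, replayable record of one differential analysis."""

    schema_version: int
    tool_version: str
    inputs: dict
    roi_healthy: dict
    roi_diseased: dict
    threshold_policy: dict
    connectivity: int
    min_region_area: int
    summary: dict
    regions: list[dict]
    main_region: dict | None
    no_suprathreshold_focus: bool
    artifacts: dict = field(default_factory=dict)
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _as_frame(obj) -> ThermalFrame:
    if isinstance(obj, ThermalFrame):
        return obj
    return read_temperature_grid(obj)


def analyze_case(
    healthy: ThermalFrame | str | Path,
    diseased: ThermalFrame | str | Path,
    roi_healthy: ROISpec,
    roi_diseased: ROISpec,
    policy: ThresholdPolicy,
    connectivity: int = 8,
    min_region_area: int = 5,
    outdir: str | Path | None = None,
    render: bool = True,
    timestamp: str | None = None,
) -> AnalysisReport:
    """Run the full differential-thermography chain on one hemiface pair.

    ``healthy``/``diseased`` may be frames or paths to temperature grids.
    The two ROIs must have identical dimensions.  When ``outdir`` is given,
    writes ``report.json``, ``regions.csv``, ``mask.png`` (label image in ROI
    coordinates), ``overlay.png`` (main region on the diseased frame) and
    ``surface.png`` (3-D differential surface); everything is computed first
    and written at the end, so no partial outputs are left on error.
    """
    h_frame = _as_frame(healthy)
    d_frame = _as_frame(diseased)
    H = extract_roi(h_frame, roi_healthy, MatrixKind.HEALTHY)
    D = extract_roi(d_frame, roi_diseased, MatrixKind.DISEASED)
    R = differential_map(D, H)
    Rp = threshold_map(R, policy)
    regions = segment_hotspots(Rp, connectivity=connectivity, min_region_area=min_region_area)

    thr = policy.delta_t_threshold
    thresholds = tuple(sorted({2.0, 3.0, float(thr)}))
    summary = asymmetry_summary(R, thresholds=thresholds)
    # JSON object keys must be strings
    summary = {
        **summary,
        "counts_ge": {str(k): v for k, v in summary["counts_ge"].items()},
        "fractions_ge": {str(k): v for k, v in summary["fractions_ge"].items()},
    }

    placement = FramePlacement(roi_diseased, mirrored=False)
    main = regions[0] if regions else None
    main_frame_pixels = (
        map_region_to_frame(main, placement, frame_shape=d_frame.temps.shape)
        if main
        else frozenset()
    )

    report = AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        tool_version=__version__,
        inputs={
            "healthy": str(healthy) if not isinstance(healthy, ThermalFrame) else "<in-memory>",
            "diseased": str(diseased) if not isinstance(diseased, ThermalFrame) else "<in-memory>",
            "healthy_meta": frame_metadata(h_frame),
            "diseased_meta": frame_metadata(d_frame),
        },
        roi_healthy=dataclasses.asdict(roi_healthy),
        roi_diseased=dataclasses.asdict(roi_diseased),
        threshold_policy=dataclasses.asdict(policy),
        connectivity=connectivity,
        min_region_area=min_region_area,
        summary=summary,
        regions=[_region_record(r) for r in regions],
        main_region=_region_record(main) if main else None,
        no_suprathreshold_focus=not regions,
        timestamp=timestamp,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / "regions.csv"
        pd.DataFrame(
            report.regions,
            columns=list(_region_record_columns()),
        ).to_csv(csv_path, index=False)
        save_label_png(label_image(regions, Rp.shape), outdir / "mask.png")
        # recorded relative to the report so a re-run elsewhere is byte-identical
        artifacts = {"regions_csv": "regions.csv", "mask_png": "mask.png"}
        if render:
            render_overlay(d_frame, main_frame_pixels, outdir / "overlay.png")
            render_surface(R, outdir / "surface.png", title="differential ΔT")
            artifacts["overlay_png"] = "overlay.png"
            artifacts["surface_png"] = "surface.png"
        report.artifacts = artifacts
        report.save(outdir / "report.json")
    return report


def _region_record_columns() -> tuple[str, ...]:
    return (
        "label",
        "area_px",
        "max_delta_t_C",
        "mean_delta_t_C",
        "centroid_row",
        "centroid_col",
        "bbox_top",
        "bbox_left",
        "bbox_height",
        "bbox_width",
        "elongation",
    )


def analyze_single_frame(
    frame: ThermalFrame | str | Path,
    axis_col: int,
    roi_height: int,
    roi_width: int,
    policy: ThresholdPolicy,
    top: int | None = None,
    diseased_side: str = "left",
    **kwargs,
) -> AnalysisReport:
    """Single-frontal-frame convenience: split about ``axis_col`` and analyze.

    Equivalent to two :func:`analyze_case` ROIs placed symmetrically about
    the sagittal midline column.
    """
    f = _as_frame(frame)
    roi_left, roi_right = hemiface_rois(f, axis_col, roi_height, roi_width, top)
    # validate the split eagerly for a clear bounds error
    split_hemifaces(f, axis_col, roi_height, roi_width, top, diseased_side)
    if diseased_side == "left":
        roi_d, roi_h = roi_left, roi_right
    else:
        roi_d, roi_h = roi_right, roi_left
    return analyze_case(f, f, roi_h, roi_d, policy, **kwargs)


_EPS = 1e-12


def compare_sessions(
    report_t1: AnalysisReport | str | Path,
    report_t2: AnalysisReport | str | Path,
) -> dict:
    """Compare two analyses of the same geometry/threshold across time.

    Returns per-session max/mean ΔT and main-region area, their changes, and
    a descriptive label: *stable* (no change), *regressing* (max ΔT and area
    both non-increasing, at least one decreasing), *progressing* (both
    non-decreasing, at least one increasing), else *mixed*.
    """
    r1 = report_t1 if isinstance(report_t1, AnalysisReport) else AnalysisReport.load(report_t1)
    r2 = report_t2 if isinstance(report_t2, AnalysisReport) else AnalysisReport.load(report_t2)

    geom1 = (r1.roi_diseased["height"], r1.roi_diseased["width"])
    geom2 = (r2.roi_diseased["height"], r2.roi_diseased["width"])
    if geom1 != geom2:
        raise ComparabilityError(f"ROI geometries differ: {geom1} vs {geom2}")
    thr1 = r1.threshold_policy["delta_t_threshold"]
    thr2 = r2.threshold_policy["delta_t_threshold"]
    if thr1 != thr2:
        raise ComparabilityError(f"threshold policies differ: {thr1} °C vs {thr2} °C")

    def _session(r: AnalysisReport) -> dict:
        return {
            "max_delta_t_C": r.summary["max_delta_t_C"],
            "mean_delta_t_C": r.summary["mean_delta_t_C"],
            "main_area_px": r.main_region["area_px"] if r.main_region else 0,
            "n_regions": len(r.regions),
        }

    s1, s2 = _session(r1), _session(r2)
    d_max = s2["max_delta_t_C"] - s1["max_delta_t_C"]
    d_area = s2["main_area_px"] - s1["main_area_px"]

    if abs(d_max) <= _EPS and d_area == 0:
        label = "stable"
    elif d_max <= _EPS and d_area <= 0:
        label = "regressing"
    elif d_max >= -_EPS and d_area >= 0:
        label = "progressing"
    else:
        label = "mixed"

    return {
        "session1": s1,
        "session2": s2,
        "delta_max_delta_t_C": d_max,
        "delta_main_area_px": d_area,
        "label": label,
        "threshold_C": thr1,
    }
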