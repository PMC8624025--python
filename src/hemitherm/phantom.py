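"""Synthetic facial thermal phantoms with ground truth.

Patient thermograms are not publishable, so every pipeline stage is
exercised on synthetic hemiface pairs that emulate the statistical premises
of the method: facial skin temperature is non-uniform but smoothly textured
(here a low-pass-filtered Gaussian random field), contralateral hemifaces
are thermally near-symmetric up to a small smooth asymmetry field plus
per-pixel sensor noise, and inflammation appears as a localized
suprathreshold elliptical focus injected into the diseased side with a known
ground-truth mask.

Generative model (all fields in °C)::

    left  = base + texture + noise_L
    right = mirror(base + texture) + asymmetry + noise_R

so the differential map of a healthy pair is ``asymmetry + noise_R +
mirror(noise_L)``, with pixel standard deviation
``sqrt(asymmetry_sigma² + 2·noise_sigma²)``; with all sigmas zero it is
exactly zero.  Texture and asymmetry fields are normalized to unit sample
standard deviation before scaling, so their amplitudes are exact per
realization.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError, RoiBoundsError
from .hotspots import threshold_for_grade
from .io import DEFAULT_BAND, ThermalFrame


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one hemiface pair.

    Defaults emulate a 350×250-pixel hemiface ROI at facial skin temperature:
    base 33.5 °C, smooth physiologic texture of 1.0 °C over a ~40-pixel
    correlation length, contralateral asymmetry of 0.3 °C (well below the
    published 2 °C moderate cut-off, as healthy faces must not trigger
    detections) and 0.1 °C per-pixel sensor noise.
    """

    height: int = 350
    width: int = 250
    base_temp: float = 33.5
    texture_amplitude: float = 1.0
    texture_scale: float = 40.0
    asymmetry_sigma: float = 0.3
    noise_sigma: float = 0.1
    seed: int = 0
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise PhantomSpecError(f"phantom must be at least 2×2, got {self.height}×{self.width}")
        if min(self.texture_amplitude, self.asymmetry_sigma, self.noise_sigma) < 0:
            raise PhantomSpecError("texture amplitude and sigmas must be ≥ 0")
        if self.texture_scale <= 0:
            raise PhantomSpecError(f"texture_scale must be positive, got {self.texture_scale}")
        spread = 3.0 * (self.texture_amplitude + self.asymmetry_sigma + self.noise_sigma)
        lo, hi = self.band
        if self.base_temp - spread < lo or self.base_temp + spread > hi:
            raise PhantomSpecError(
                f"base {self.base_temp} ± 3·(texture+asymmetry+noise) = ±{spread:.2f} °C "
                f"leaves the plausibility band [{lo}, {hi}] °C"
            )


@dataclass(frozen=True)
class HotspotSpec:
    """An elliptical inflammation focus.

    ``semi_axes`` are the (row, col) semi-axes in pixels and ``orientation``
    rotates the major axis in radians.  ``profile='plateau'`` adds the full
    ``amplitude`` inside the ellipse (sharp-bounded inflamed core, the
    default); ``'gaussian'`` decays as ``amplitude·exp(−ρ²/2)`` with ρ the
    normalized elliptical radius, so the ellipse marks the 1-σ contour.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0
    amplitude: float = 3.5
    profile: str = "plateau"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise PhantomSpecError(f"hotspot amplitude must be positive, got {self.amplitude}")
        if min(self.semi_axes) <= 0:
            raise PhantomSpecError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.profile not in ("gaussian", "plateau"):
            raise PhantomSpecError(f"profile must be 'gaussian' or 'plateau', got {self.profile!r}")


@dataclass(frozen=True)
class PhantomCase:
    """A paired healthy/diseased phantom with ground truth."""

    healthy_frame: ThermalFrame
    diseased_frame: ThermalFrame
    truth_mask: np.ndarray
    spec: PhantomSpec
    hotspot: HotspotSpec
    threshold_used: float
    grade: str
    diseased_side: str


def _smooth_unit_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Low-pass-filtered white noise, centered and scaled to unit sample std."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    f -= f.mean()
    s = f.std()
    if s == 0:  # pathological (constant field); avoid 0/0
        return np.zeros(shape)
    return f / s


def generate_baseline(spec: PhantomSpec) -> tuple[ThermalFrame, ThermalFrame]:
    """Generate a healthy (left, right) hemiface pair.

    The right frame is the mirror of the left frame's shared structure plus
    an asymmetry field and independent sensor noise.  A fixed seed yields
    bit-identical output; with ``asymmetry_sigma = noise_sigma = 0`` the
    differential map of the pair is exactly zero.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    # draw all fields in a fixed order so the stream is stable across sigmas
    texture = _smooth_unit_field(rng, shape, spec.texture_scale)
    asym = _smooth_unit_field(rng, shape, spec.texture_scale)
    noise_l = rng.standard_normal(shape)
    noise_r = rng.standard_normal(shape)

    structure = spec.base_temp + spec.texture_amplitude * texture
    left = structure + spec.noise_sigma * noise_l
    right = structure[:, ::-1] + spec.asymmetry_sigma * asym + spec.noise_sigma * noise_r
    sid = f"phantom-seed{spec.seed}"
    return (
        ThermalFrame(left, band=spec.band, subject_id=f"{sid}-L"),
        ThermalFrame(right, band=spec.band, subject_id=f"{sid}-R"),
    )


def _elliptical_radius_sq(shape, hs: HotspotSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - hs.center[0]
    dx = cc - hs.center[1]
    cos_t, sin_t = math.cos(hs.orientation), math.sin(hs.orientation)
    a, b = hs.semi_axes
    u = (dy * cos_t + dx * sin_t) / a
    v = (-dy * sin_t + dx * cos_t) / b
    return u * u + v * v


def _check_ellipse_in_frame(shape, hs: HotspotSpec) -> None:
    a, b = hs.semi_axes
    cos_t, sin_t = math.cos(hs.orientation), math.sin(hs.orientation)
    ext_r = math.hypot(a * cos_t, b * sin_t)
    ext_c = math.hypot(a * sin_t, b * cos_t)
    cy, cx = hs.center
    if (
        cy - ext_r < 0
        or cy + ext_r > shape[0] - 1
        or cx - ext_c < 0
        or cx + ext_c > shape[1] - 1
    ):
        raise RoiBoundsError(
            f"hotspot ellipse (center {hs.center}, extent ±({ext_r:.1f}, {ext_c:.1f})) "
            f"overhangs the {shape[0]}×{shape[1]} frame"
        )


def hotspot_increment(shape: tuple[int, int], hs: HotspotSpec) -> np.ndarray:
    """Temperature increment field (°C) that :func:`inject_hotspot` adds."""
    rho2 = _elliptical_radius_sq(shape, hs)
    if hs.profile == "plateau":
        return np.where(rho2 <= 1.0, hs.amplitude, 0.0)
    return hs.amplitude * np.exp(-rho2 / 2.0)


def inject_hotspot(
    frame: ThermalFrame,
    hs: HotspotSpec,
    threshold_for_truth: float,
    truth_rule: str = "threshold",
) -> tuple[ThermalFrame, np.ndarray]:
    """Add an elliptical focus to ``frame``; return the new frame and truth mask.

    The default truth rule marks pixels whose *injected increment* is ≥
    ``threshold_for_truth`` — exactly the set the differential procedure
    should recover at that cut-off; ``truth_rule='half_max'`` instead marks
    increments ≥ amplitude/2.
    """
    _check_ellipse_in_frame(frame.temps.shape, hs)
    inc = hotspot_increment(frame.temps.shape, hs)
    if truth_rule == "threshold":
        truth = inc >= threshold_for_truth
    elif truth_rule == "half_max":
        truth = inc >= hs.amplitude / 2.0
    else:
        raise PhantomSpecError(f"truth_rule must be 'threshold' or 'half_max', got {truth_rule!r}")
    out = ThermalFrame(
        frame.temps + inc,
        emissivity=frame.emissivity,
        capture_time=frame.capture_time,
        subject_id=frame.subject_id,
        band=frame.band,
    )
    return out, truth


def default_hotspot(spec: PhantomSpec, amplitude: float = 3.5, profile: str = "plateau") -> HotspotSpec:
    """An elongated island-shaped focus sized to the phantom (cheek-like)."""
    return HotspotSpec(
        center=(spec.height * 0.5, spec.width * 0.5),
        semi_axes=(spec.height * 0.26, spec.width * 0.20),
        orientation=0.5,
        amplitude=amplitude,
        profile=profile,
    )


def generate_case(
    spec: PhantomSpec,
    hs: HotspotSpec | None = None,
    grade: str = "severe",
    diseased_side: str = "left",
    truth_rule: str = "threshold",
) -> PhantomCase:
    """Baseline pair plus a hotspot injected into the diseased side.

    ``threshold_used`` comes from the severity grade (severe → 3 °C,
    moderate → 2 °C); the truth mask is expressed in the diseased frame's
    pixel coordinates.  Deterministic under a fixed ``spec.seed``.
    """
    if diseased_side not in ("left", "right"):
        raise PhantomSpecError(f"diseased_side must be 'left' or 'right', got {diseased_side!r}")
    policy = threshold_for_grade(grade)
    if hs is None:
        hs = default_hotspot(spec)
    left, right = generate_baseline(spec)
    if diseased_side == "left":
        diseased, truth = inject_hotspot(left, hs, policy.delta_t_threshold, truth_rule)
        healthy = right
    else:
        diseased, truth = inject_hotspot(right, hs, policy.delta_t_threshold, truth_rule)
        healthy = left
    return PhantomCase(
        healthy_frame=healthy,
        diseased_frame=diseased,
        truth_mask=truth,
        spec=spec,
        hotspot=hs,
        threshold_used=policy.delta_t_threshold,
        grade=policy.grade or grade,
        diseased_side=diseased_side,
    )


def case_metadata(case: PhantomCase) -> dict:
    """Serializable generation metadata (all spec fields + seed) for replay."""
    return {
        "spec": asdict(case.spec),
        "hotspot": asdict(case.hotspot),
        "grade": case.grade,
        "diseased_side": case.diseased_side,
        "threshold_used_C": case.threshold_used,
        "truth_pixels": int(case.truth_mask.sum()),
    }
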