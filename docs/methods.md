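# Methods

## The differential procedure

The method assumes that healthy faces are thermally near-symmetric across
the sagittal midline, and that an inflammatory focus raises skin temperature
locally on one hemiface. With equally sized ROIs ⟨H⟩ (healthy) and ⟨D⟩
(diseased), the mirrored healthy matrix ⟨H\*⟩ᵢⱼ = h_{i,n−1−j} puts
contralateral pixels into correspondence, and ⟨R⟩ = ⟨D⟩ − ⟨H\*⟩ is the
pixel-wise thermal excess attributable to disease. Thresholding zeroes every
Rᵢⱼ **strictly below** ΔT_threshold: a value exactly equal to the cut-off
survives. Negative differentials (diseased side cooler) are therefore always
zeroed; the signed map is retained pre-threshold for diagnostics
(`asymmetry_summary`). The two clinical cut-offs are fixed constants:
severe → 3.0 °C, moderate → 2.0 °C.

Assumptions worth stating explicitly:

* **Pixel correspondence is given.** ROIs must have identical dimensions and
  are subtracted index-by-index; no registration, scaling or pose correction
  is performed. How well the two ROIs correspond anatomically is the
  operator's responsibility, and is the method's main practical limitation
  (strong facial deformity or oblique camera angles break it).
* **Calibrated input.** Temperatures arrive already in °C; emissivity
  (default 0.98, human skin) is metadata, not a correction applied here.
* **Lateral disease.** A median or paramedian focus contaminates both
  hemifaces and cannot be isolated by contralateral subtraction; such cases
  are out of scope.

## Coordinate and geometry conventions

Row-major, 0-based indices, origin top-left, half-open ranges. The ROI size
350×250 used throughout the validation is read as rows×columns. In
single-frontal-frame mode the midline `axis_col` is interpreted as the
boundary between columns `axis_col−1` and `axis_col`: the left ROI spans
columns `[axis_col−w, axis_col)`, the right `[axis_col, axis_col+w)`. With
that convention a frame built by abutting the two profile ROIs reproduces
the two-profile differential exactly (tested). The midline is user-supplied;
no automatic face-landmark detection is attempted.

## Segmentation choices

Connected components of the suprathreshold set use 8-connectivity by
default (inflammation contours are smooth, and observed suprathreshold
regions are single elongated islands); 4-connectivity is available.
Components below `min_region_area` (default 5 px) are discarded to suppress
single-pixel noise survivors; 0 disables despeckling. The main site is the
largest region, ties broken by higher max ΔT then by top-left-most centroid,
so ordering is deterministic. Elongation is the square-root ratio of the
principal second moments of the pixel set with each pixel treated as a unit
square (adds 1/12 per axis): a single pixel or any square block scores 1.0,
a 1×k line scores k. It quantifies "elongated" vs "compact" descriptively;
no shape taxonomy is claimed.

## The phantom generator

Real patient thermograms cannot be redistributed, so validation runs on
synthetic hemiface pairs built from the same statistical premises the
method relies on:

    left  = base + texture + noise_L
    right = mirror(base + texture) + asymmetry + noise_R

* `base_temp` 33.5 °C — facial skin temperature.
* `texture` — smooth physiologic non-uniformity: low-pass-filtered white
  noise (Gaussian kernel, `texture_scale` 40 px ≈ 1 cm at the camera
  resolution the defaults emulate), normalized to unit sample std and scaled
  by `texture_amplitude` 1.0 °C. It is *shared* between the hemifaces and
  cancels exactly in the differential.
* `asymmetry` — a smooth field of the same correlation length, std
  `asymmetry_sigma` 0.3 °C, applied to one side only. 0.3 °C is an artifact
  calibration chosen well below the 2 °C moderate cut-off (healthy faces
  must not trigger detections), not a literature value: no quantitative
  healthy-face asymmetry distribution is published.
* `noise` — i.i.d. per-pixel sensor noise, `noise_sigma` 0.1 °C, independent
  per hemiface.

The differential of a healthy pair is `asymmetry + noise_R + mirror(noise_L)`
with per-pixel std √(σ_asym² + 2σ_noise²) ≈ 0.33 °C (verified against
simulation over 50 seeds); with all sigmas zero it is exactly zero, which
makes the noiseless-recovery test pixel-exact. All fields are drawn from a
single seeded generator in a fixed order, so output is bit-reproducible and
stable as individual sigmas are set to zero.

The injected focus is a rotated ellipse, default semi-axes (0.26·h, 0.20·w)
= (91, 50) px at the default 350×250 size, orientation 0.5 rad — an
elongated island emulating a cheek focus. The default profile is a
**plateau** (the full amplitude inside the ellipse): it models a fully
inflamed core with a sharp suprathreshold boundary and makes the ground
truth well-posed — the truth mask (pixels whose injected increment ≥ the
cut-off) is exactly the ellipse. A `gaussian` profile
(amplitude·exp(−ρ²/2), ellipse = 1 σ contour) is available for smoother
foci, along with a half-maximum truth rule. Default amplitude 3.5 °C sits
above the severe cut-off, matching a severe presentation.

What the phantom does **not** emulate: vascular anatomy, bioheat (Pennes)
diffusion from deep foci, facial geometry/perspective effects, emissivity
angle errors, or ROI misregistration. Passing the recovery tests therefore
demonstrates the correctness of the processing chain under the stated
statistical model, not clinical performance on real thermograms.

## Validation conditions and observed behaviour

The recovery study uses 20 seeds at the defaults (350×250, σ_asym 0.3,
σ_noise 0.1, plateau 3.5 °C, severe cut-off). The main detected region then
matches the truth mask with Dice ≈ 0.97–0.99 in most seeds; occasionally a
low patch of the smooth asymmetry field carves the plateau into two
components and the main region's Dice drops to ≈ 0.75. The detected peak ΔT
overestimates the injected amplitude by the expected maximum of the
asymmetry+noise field over the plateau (≈ 0.8 °C over ~14 000 px); the mean
across seeds stays within 3·√(σ_asym² + 2σ_noise²) of 3.5 °C, which is the
tolerance the recovery test asserts. Healthy pairs produce no suprathreshold
region at the 2 °C cut-off (the smooth asymmetry field's maxima stay near
1–1.5 °C at these sizes).

## Numerical and I/O choices

* Text grids are written with Python's shortest exact float representation,
  so write→read round-trips are bit-exact; `nan` marks invalid pixels, which
  propagate through subtraction and are excluded from statistics,
  segmentation and rendering. Decimal-comma/semicolon dialects are supported
  for European thermography exports.
* The plausibility band [15, 45] °C brackets facial skin plus fever and
  cool-ambient margins; a finite out-of-band value in a text grid is an
  error, while out-of-band *calibrated* radiometric pixels are masked as
  sensor artefacts (an all-invalid result is an error).
* Radiometric conversion is affine (T = gain·DN + offset) with an optional
  invalid-value sentinel; gain must be nonzero. No atmospheric, distance or
  emissivity-angle corrections are attempted.
* Overlay rendering happens at native raster resolution (colormapped RGB
  assembled in memory, written with Pillow), so outputs are deterministic
  byte-for-byte and the contour provably leaves pixels outside the dilated
  mask untouched. The default palette is perceptually uniform (inferno);
  rainbow/jet are available as a legacy option.
* Analysis reports record every parameter affecting output; artifact paths
  are stored relative to the report and wall-clock timestamps are opt-in
  (`--timestamp`), so a fixed input reproduces byte-identical reports.

## Known limitations

Beyond the scope exclusions above: the severity grade must be supplied by
the clinician (the tool maps it to a cut-off; it does not grade), the
elongation descriptor is rotation-variant for regions touching the ROI
border, and session comparison labels ("stable"/"regressing"/"progressing")
are descriptive arithmetic on area and peak ΔT, not a validated clinical
outcome measure.
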