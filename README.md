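# hemitherm

Differential medical infrared thermography (MIT) for localizing facial
inflammation — in particular odontogenic facial cellulitis, which is
predominantly lateral and hemifacial. In a healthy face the two hemifaces
are thermally near-symmetric, so the skin-temperature excess caused by an
inflammatory focus can be isolated by comparing a diseased hemiface with the
mirrored healthy one.

`hemitherm` is a library + CLI for clinicians' technical collaborators and
imaging researchers. It works on calibrated skin-temperature rasters (plain
text grids of °C, or raw 16-bit radiometric images plus an affine
calibration) and ships a synthetic thermal-phantom generator with ground
truth, so the whole pipeline can be exercised and validated without patient
data.

## The method

Given equally sized rectangular ROIs over the healthy and diseased
hemifaces, expressed as m×n temperature matrices ⟨H⟩ and ⟨D⟩ (°C per pixel):

1. **Mirror** the healthy matrix about its vertical axis so contralateral
   pixels correspond: ⟨H\*⟩ᵢⱼ = h_{i, n−1−j} (0-based).
2. **Subtract** pixel-wise to obtain the differential map ⟨R⟩ = ⟨D⟩ − ⟨H\*⟩.
3. **Threshold** by clinical severity: R′ᵢⱼ = 0 where Rᵢⱼ < ΔT_threshold,
   with ΔT_threshold = 3 °C for severe and 2 °C for moderate inflammation
   (values exactly equal to the cut-off survive).
4. **Segment** the suprathreshold pixels into connected components
   (8-connectivity by default, min region area 5 px); the largest is the
   main inflammation site. Each region carries area, max/mean ΔT, centroid,
   bounding box and an elongation descriptor.
5. **Reposition** the detected region into full-frame coordinates and render
   an overlay plus a 3-D ΔT surface.

Longitudinal monitoring compares two analyses of the same geometry and
threshold (e.g. admission vs a 48 h control) and labels the evolution
stable / regressing / progressing.

## Worked example

Generate a synthetic case — a 350×250 hemiface pair at 33.5 °C base
temperature with smooth physiologic texture, 0.3 °C contralateral asymmetry,
0.1 °C sensor noise and a 3.5 °C elliptical focus injected into the diseased
side — then run the severe-grade analysis:

```bash
hemitherm phantom --seed 42 -o case
cat > roi.yaml <<EOF
healthy:  {top: 0, left: 0, height: 350, width: 250}
diseased: {top: 0, left: 0, height: 350, width: 250}
EOF
hemitherm analyze --healthy case/healthy.csv --diseased case/diseased.csv \
    --roi roi.yaml --grade severe -o out
```

which prints

```
main region: area 14259 px, max ΔT 4.17 °C, centroid (175.0, 125.0)
out/report.json
```

One connected suprathreshold region was found: 14 259 pixels whose
diseased-minus-mirrored-healthy difference reaches 4.17 °C at its hottest
pixel — the injected 3.5 °C plateau plus the upper tail of asymmetry and
noise — centred at ROI pixel (175, 125), where the phantom's focus was
placed. `out/` contains `report.json` (every parameter needed to re-run),
`regions.csv`, `mask.png` (label image), `overlay.png` (region contour on
the diseased frame) and `surface.png` (3-D ΔT surface).

Comparing a session against itself shows the longitudinal report format:

```bash
hemitherm compare --t1 out/report.json --t2 out/report.json
# → "label": "stable", delta_main_area_px 0, delta_max_delta_t_C 0.0
```

A lower-amplitude follow-up case would report `"regressing"` (area and peak
ΔT both down); a new suprathreshold focus reports `"progressing"`.

## Scope

The package implements the thermal image-processing chain only. It does not
perform face-midline detection, image registration (ROI pixel
correspondence is the caller's responsibility), thermal-to-photograph or CT
registration, median/paramedian cellulitis handling, or any clinical
decision scoring. See `docs/methods.md` for the model, parameter choices and
limitations.
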