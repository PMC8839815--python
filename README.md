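# swimarea

Automated estimation of a swimmer's projected (frontal or lateral)
surface area from underwater colour video, frame by frame, with the
downstream analyses a tethered-swimming session calls for: stroke-cycle
frequency extraction, frontal-vs-lateral regression, and a quadratic
resistive-force model.

## Why

The hydrodynamic resistive force on a swimmer follows, in steady state,

    F_R = ½ · C_R · A · ρ · v²

where `A` is the projected frontal area, `ρ` the water density, `v` the
forward velocity and `C_R` a dimensionless drag coefficient. `A`
fluctuates within every stroke cycle, so time-resolved drag estimation
needs `A` per video frame — at 30 Hz, far beyond what manual outlining
can deliver. This package segments the swimmer's silhouette
automatically and counts its pixels:

1. crop a region of interest;
2. detect swimwear, cap and harness pixels with a CIELAB box threshold
   (frontal defaults `25.466 < L < 98.620`, `−46.336 < a < 8.860`,
   `−31.446 < b < 60.616`) and repaint them with a skin-like chest
   colour, RGB (27, 131, 135), so dark garments don't split the body;
3. keep only pixels with normalised lightness `5 < L* < 160` (water and
   bright furniture fall outside) and drop everything above the water
   line (row 97 of the ROI), which removes the mirrored surface
   reflection;
4. Otsu-binarise the background-suppressed grayscale ROI, remove blobs
   under 3000 px, fill internal holes, and count the surviving pixels.

Real pool footage from the original study is not distributable, so the
package ships a synthetic pool-scene renderer (water, lane ropes, water
line with attenuated reflection, skin/swimwear/cap swimmer) with exact
ground-truth silhouettes, used by the test suite to score the pipeline
end to end.

## Worked example

```python
from swimarea import SceneSpec, render_scene, process_frame, frontal_config
from swimarea import DragParams, resistive_force, pixels_to_m2

frame, truth = render_scene(SceneSpec(seed=3))      # synthetic scene + truth
result = process_frame(frame, frontal_config())     # full pipeline
print("ground-truth area:", truth.area_pixels, "px")
print("estimated area:   ", result.area_pixels, "px")

area_m2 = pixels_to_m2(result.area_pixels, pixel_scale_mm2=6.23)
force = resistive_force(DragParams(c_r=0.3, rho=1000.0), area_m2, velocity_mps=1.6)
print("area:", round(area_m2, 4), "m^2")
print("resistive force:", round(force, 1), "N")
```

prints

```
ground-truth area: 6685 px
estimated area:    6685 px
area: 0.0416 m^2
resistive force: 16.0 N
```

The estimated area equals the rendered silhouette exactly here; across
20 seeded scenes the relative error stays below 5% (in practice below
0.1%). The pixel→m² scale (6.23 mm²/px) and the drag coefficient are
per-installation calibration inputs, not outputs of this package.

## Command line

```sh
swimarea simulate --out scenes/ --n-frames 1800 --freq 0.476 --seed 1
swimarea segment scenes/ --camera frontal --out run/
swimarea analyze run/area_frontal.csv --out report.json
swimarea overlay scenes/ --out overlays/       # red-mask overlay PNGs
```

`segment` writes a per-frame CSV (`frame_index,time_s,area_pixels,warnings`);
`analyze` writes a JSON report with the dominant stroke frequency per
camera and, given two CSVs, the least-squares regression (slope,
intercept, R²) between the cameras' areas. Camera configurations are
YAML files (`--config`); the shipped frontal defaults carry the
constants listed above verbatim.

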