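# Methods

## Segmentation model

The pipeline assumes a stationary (tethered) swimmer filmed head-on or
side-on by a fixed underwater camera, so one static configuration of
colour thresholds and geometry per camera suffices for a whole
recording. Per frame:

1. **ROI crop.** Optional; restricts all later work to the region the
   swimmer occupies. Coordinates are 0-based with the top row at 0 and
   half-open extents.
2. **Garment replacement.** Swimwear, cap and harness are dark and
   would merge with the suppressed background after binarisation. A
   CIELAB box threshold (strict inequalities on L, a, b) marks those
   pixels, which are repainted with a flat chest-skin colour. The
   frontal defaults are `25.466 < L < 98.620`, `−46.336 < a < 8.860`,
   `−31.446 < b < 60.616` and replacement RGB (27, 131, 135). No
   lateral-specific constants were published; the lateral defaults
   equal the frontal ones and are expected to be customised per
   installation via the YAML config.
3. **Water removal.** The lightness channel of the repainted frame is
   normalised to L\* = L·255/100 and only pixels with `5 < L* < 160`
   are kept. The *keep-in-range* reading is used: swimmer skin and the
   chest replacement colour sit mid-range while bright, well-lit water
   sits above it. Both bounds are strict.
4. **Water-line cut.** All rows above the water line are zeroed,
   removing the swimmer's mirrored surface reflection. The config
   stores the water-line row in the 1-based convention the published
   constant uses (97); internally rows with 0-based index < 96 are
   discarded.
5. **Binarisation.** The kept region of the BT.601 grayscale frame
   (suppressed pixels set to 0, making water the dark class) is split
   by Otsu's global threshold: the level `T ∈ {0..255}` maximising the
   between-class variance of `{v ≤ T}` vs `{v > T}`, lowest maximiser
   on ties, foreground = `v > T`. A constant raster yields an all-zero
   mask plus a warning. If binarisation ever puts more than half of the
   ROI in the foreground (a dark-swimmer/bright-water inversion), the
   polarity is flipped within the kept region and a warning logged.
6. **Blob filter, hole fill, count.** 8-connected components smaller
   than `min_blob_area` (default 3000 px) are removed; background
   regions not 4-connected to the raster border are filled (the
   standard complementary connectivity pair); the area is the final
   mask's pixel count.

Degenerate frames (nothing kept, nothing above threshold, no surviving
blob) report area 0 with a warning code — `constant_roi`,
`polarity_inverted`, `no_blobs` — rather than raising, so a 60-s batch
run survives occasional bad frames.

### Colour conventions

CIELAB uses sRGB companding with the D65 reference white, tristimulus
(Xn, Yn, Zn) = (0.95047, 1.0, 1.08883) — the convention consumer
cameras assume. L is kept on its native 0–100 scale so the garment
thresholds apply verbatim; `normalize_lightness` is the explicit bridge
to the 0–255 scale on which the water interval is expressed. Grayscale
uses ITU-R BT.601 luma weights (0.2989, 0.5870, 0.1140) with
half-away-from-zero rounding. `a` and `b` are unclipped floats.

## Time-series analyses

An `AreaSeries` is a uniformly sampled area-vs-time record (nominal
30 Hz). Analyses:

- **Regression.** Ordinary least squares of one camera's areas on the
  other's, paired by frame index; R² is the squared Pearson
  correlation. A constant predictor is an error; a constant response
  yields R² = 0 with a warning, so batch runs survive degenerate
  trials.
- **Spectrum.** Mean-removed, rectangular-window DFT magnitude
  (`|X_k|`, single-sided), zero-padded by a factor of 8 by default.
  Padding interpolates the spectrum onto a grid of width
  `fs / (8·N)` Hz — about 0.002 Hz for a 60-s record — which is what
  makes sub-millihertz peak localisation of a ~0.5 Hz stroke cadence
  meaningful. The dominant frequency is the largest magnitude at or
  above `min_hz` (default 0.1 Hz, excluding residual DC leakage), ties
  broken toward the lower frequency.
- **Drag model.** `F_R = ½ C_R A ρ v²` with `A` in m² (a fixed
  mm²-per-pixel scale converts pixel counts; the scale and `C_R` come
  from external calibration, e.g. a velocity-perturbation protocol).
  The Newtonian balance `m·a = F_P + F_R` treats `F_R` as signed —
  negative when opposing forward motion — so constant speed is
  literally `F_P = −F_R`.

## Synthetic scene generator

The renderer emulates the elements the segmentation must handle: flat
bluish-green water, two bright lane-rope stripes, a water line with a
mirrored reflection of the swimmer above it (blended 30% toward the
water colour), and a swimmer composed of a torso ellipse, head disc and
two angled arm rectangles, painted skin / swimwear / cap. Per-channel
i.i.d. Gaussian noise (default sd 3, clipped to [0, 255]) adds minimal
sensor realism. Ground truth is the exact rasterised silhouette;
reflections are never counted.

Default colours were fixed once from the shipped thresholds so every
mechanism is exercised rather than bypassed: water (0, 215, 170) falls
outside the garment box (a = −54.6) and outside the L\* keep range
(L\* = 196); lane yellow (230, 200, 40) likewise; skin (180, 130, 100)
falls inside the keep range (L\* = 149); swimwear (80, 62, 60) and cap
(70, 70, 70) fall inside the garment box and get repainted. A genuinely
saturated dark red would have a ≈ 15–40 and miss the garment box's
a < 8.860 bound, so the default swimwear is a desaturated maroon — the
closest colour the published box actually captures.

Sequences modulate the silhouette's linear scale by
`sqrt(1 + A·sin(2πft + φ))`, so the true area oscillates sinusoidally
at `f` (default amplitude 0.15, i.e. ±15% area — a plausible
within-stroke fluctuation). The phase offset lets two-camera
demonstrations avoid artificial phase locking.

**What passing tests do and do not show.** The generator has flat
region colours, no articulation, no refraction, caustics, bubbles or
illumination gradients. Passing the ≤5% end-to-end area criterion shows
the algorithm chain is implemented correctly and that the published
constants separate the intended colour classes; it does not show
robustness to real optical conditions, which require per-installation
threshold calibration.

## Numerical and design choices

- Binarisation reference: the original description cites an unnamed
  standard method; Otsu's between-class-variance criterion is adopted,
  implemented directly over the 256 candidate levels (and
  cross-checked against an exhaustive search and scikit-image in the
  tests).
- All threshold comparisons are strict; boundary-equal values are
  excluded.
- Default frame size for synthetic work is 240×320 (the published
  water-line row 97 and the 3000-px blob threshold still bind at this
  size); full-HD frames work unchanged but render and segment more
  slowly.
- Timestamps default to `frame_index / 30.0` when a container provides
  none; the rate is overridable.
- CSV/JSON outputs are deterministic (fixed column order, sorted JSON
  keys) so identical inputs give byte-identical artifacts.

## Limitations

- One swimmer per scene; no tracking of a moving swimmer.
- The drag coefficient, pixel scale and velocity are inputs, not
  estimates; the steady-state drag equation applied to unsteady motion
  bounds the physical fidelity of any force numbers.
- The stroke-frequency estimator assumes a dominant single cadence;
  multi-modal spectra return only the largest peak.
- Video-container ingestion depends on an imageio backend being
  available; directories of numbered images are the first-class input.
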