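"""Colour-space conversions used by the segmentation masks.

All masks operate either in CIELAB (garment detection) or on a
normalised lightness channel (water removal), so the conversions here
fix the colour conventions for the whole pipeline:

* CIELAB uses the sRGB companding curve and the D65 reference white
  (Xn, Yn, Zn) = (0.95047, 1.0, 1.08883) — the convention consumer
  cameras assume. L is kept on its native 0–100 scale; ``a`` and ``b``
  are unclipped floats.
* ``normalize_lightness`` maps L affinely onto 0–255, the scale on which
  the water-removal interval is expressed.
* Grayscale uses ITU-R BT.601 luma weights (0.2989 R + 0.5870 G +
  0.1140 B), rounded half away from zero to an integer raster.
"""

from __future__ import annotations

import numpy as np
from skimage import color

#: BT.601 luma weights (R, G, B).
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    """Check an RGB raster: H×W×3, H,W ≥ 1, channels in [0, 255]."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB raster, got shape {frame.shape}")
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError("empty raster: height and width must be >= 1")
    if frame.min() < 0 or frame.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return frame


def rgb_to_lab(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame (integers in [0, 255]) to CIELAB.

    Returns an H×W×3 float array with L in [0, 100] and a, b unclipped.
    Gray inputs (R=G=B) map onto the neutral axis (a ≈ 0, b ≈ 0).
    """
    frame = _validate_frame(frame)
    return color.rgb2lab(frame.astype(np.uint8))


def normalize_lightness(lab: np.ndarray) -> np.ndarray:
    """Map the L channel of a Lab frame from [0, 100] onto [0, 255].

    Accepts either an H×W×3 Lab array (the L channel is extracted) or a
    bare H×W lightness array. The map is affine: L* = L × 255 / 100.
    """
    lab = np.asarray(lab, dtype=float)
    lightness = lab[..., 0] if lab.ndim == 3 else lab
    return lightness * (255.0 / 100.0)


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """BT.601 luma grayscale of an RGB frame, as integers in [0, 255].

    Rounding is half away from zero, so pure gray inputs map to
    themselves.
    """
    frame = _validate_frame(frame).astype(float)
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * frame[..., 0] + wg * frame[..., 1] + wb * frame[..., 2]
    return np.floor(luma + 0.5).astype(np.uint8)
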