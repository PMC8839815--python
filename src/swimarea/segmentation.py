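"""Per-frame silhouette extraction and pixel-area measurement.

The pipeline, applied to every video frame:

1. crop the region of interest (ROI);
2. detect swimwear/cap/harness pixels by a CIELAB box threshold and
   repaint them with a skin-like chest colour, so dark garments do not
   split the silhouette;
3. keep only pixels whose normalised lightness L* falls in the water
   mask interval (water and bright pool furniture fall outside it);
4. discard everything above the water line, which removes the mirrored
   surface reflection of the swimmer;
5. binarise the background-suppressed grayscale ROI with Otsu's global
   threshold, drop connected components smaller than a minimum blob
   area, fill internal holes, and count the remaining pixels.

Coordinates are 0-based with the top row at index 0. The configuration
stores the water-line row in the 1-based convention the printed
constants use; the conversion happens inside :func:`process_frame`.
All threshold comparisons are strict, matching the printed intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from swimarea.colorspace import (
    _validate_frame,
    normalize_lightness,
    rgb_to_gray,
    rgb_to_lab,
)

__all__ = [
    "ROISpec",
    "LabThreshold",
    "SegmentationConfig",
    "FrameResult",
    "SegmentationWarning",
    "frontal_config",
    "lateral_config",
    "crop_roi",
    "threshold_mask",
    "replace_pixels",
    "water_mask",
    "waterline_filter",
    "otsu_threshold",
    "binarise",
    "filter_blobs",
    "fill_holes",
    "count_area",
    "process_frame",
]


class SegmentationWarning(UserWarning):
    """Raised (as a warning) for degenerate frames that yield no area."""


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned crop window: 0-based top/left, half-open extent."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top and left must be >= 0")


@dataclass(frozen=True)
class LabThreshold:
    """Open box in CIELAB space; a pixel matches iff strictly inside."""

    l_range: tuple[float, float]
    a_range: tuple[float, float]
    b_range: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("L", self.l_range),
            ("a", self.a_range),
            ("b", self.b_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} interval must have min < max, got ({lo}, {hi})")


@dataclass
class SegmentationConfig:
    """All per-camera constants of the area-detection pipeline.

    ``waterline_row`` is stored 1-based (the convention of the published
    constants, i = 97): silhouette rows with 1-based index >= the stored
    value are retained. ``roi = None`` processes the full frame.
    """

    garment_threshold: LabThreshold
    replacement_rgb: tuple[int, int, int]
    water_lstar_range: tuple[float, float]
    waterline_row: int
    min_blob_area: int
    camera_label: str = "frontal"
    roi: ROISpec | None = None

    def __post_init__(self) -> None:
        if self.min_blob_area < 0:
            raise ValueError("min_blob_area must be >= 0")
        if self.waterline_row < 1:
            raise ValueError("waterline_row is 1-based and must be >= 1")
        if any(not 0 <= c <= 255 for c in self.replacement_rgb):
            raise ValueError("replacement_rgb channels must lie in [0, 255]")
        lo, hi = self.water_lstar_range
        if not lo < hi:
            raise ValueError("water_lstar_range must have min < max")


@dataclass
class FrameResult:
    """Outcome of the pipeline on one frame."""

    area_pixels: int
    final_mask: np.ndarray
    frame_index: int = 0
    warnings: list[str] = field(default_factory=list)


# Published frontal-camera constants: garment CIELAB box, chest
# replacement colour, L* keep interval, water-line row (1-based) and
# minimum blob area.
_FRONTAL = SegmentationConfig(
    garment_threshold=LabThreshold(
        l_range=(25.466, 98.620),
        a_range=(-46.336, 8.860),
        b_range=(-31.446, 60.616),
    ),
    replacement_rgb=(27, 131, 135),
    water_lstar_range=(5.0, 160.0),
    waterline_row=97,
    min_blob_area=3000,
    camera_label="frontal",
)


def frontal_config() -> SegmentationConfig:
    """Default frontal-camera configuration (the published constants)."""
    return replace(_FRONTAL)


def lateral_config() -> SegmentationConfig:
    """Default lateral-camera configuration.

    No separate lateral constants were published; the defaults equal the
    frontal ones and are meant to be customised per installation.
    """
    return replace(_FRONTAL, camera_label="lateral")


def crop_roi(frame: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Extract the ROI of a frame as a copy."""
    frame = _validate_frame(frame)
    h, w = frame.shape[:2]
    if roi.top + roi.height > h:
        raise ValueError(
            f"ROI bottom edge {roi.top + roi.height} exceeds frame height {h}"
        )
    if roi.left + roi.width > w:
        raise ValueError(
            f"ROI right edge {roi.left + roi.width} exceeds frame width {w}"
        )
    return frame[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()


def threshold_mask(lab: np.ndarray, t: LabThreshold) -> np.ndarray:
    """Mask of pixels strictly inside the CIELAB box ``t``."""
    lab = np.asarray(lab, dtype=float)
    l_ch, a_ch, b_ch = lab[..., 0], lab[..., 1], lab[..., 2]
    return (
        (t.l_range[0] < l_ch)
        & (l_ch < t.l_range[1])
        & (t.a_range[0] < a_ch)
        & (a_ch < t.a_range[1])
        & (t.b_range[0] < b_ch)
        & (b_ch < t.b_range[1])
    )


def replace_pixels(
    frame: np.ndarray, mask: np.ndarray, rgb: Sequence[int]
) -> np.ndarray:
    """Repaint masked pixels with a flat colour; others are untouched."""
    frame = _validate_frame(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame {frame.shape[:2]}"
        )
    out = frame.copy()
    out[mask] = np.asarray(rgb, dtype=frame.dtype)
    return out


def water_mask(lstar: np.ndarray, lstar_range: tuple[float, float]) -> np.ndarray:
    """Mask of pixels to KEEP: normalised lightness strictly in range.

    Pixels outside the interval are water/background and are removed.
    """
    lstar = np.asarray(lstar, dtype=float)
    lo, hi = lstar_range
    return (lo < lstar) & (lstar < hi)


def waterline_filter(mask: np.ndarray, waterline_row: int) -> np.ndarray:
    """Zero all rows above the water line (0-based row < waterline_row).

    Removes the swimmer's mirrored reflection at the water surface.
    """
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= waterline_row <= mask.shape[0]:
        raise ValueError(
            f"waterline_row {waterline_row} outside mask height {mask.shape[0]}"
        )
    out = mask.copy()
    out[:waterline_row] = False
    return out


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's global threshold over candidate levels 0–255.

    Returns the level T maximising the between-class variance of the
    split {value <= T} vs {value > T}; the lowest maximiser wins ties.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    hist = np.bincount(gray.astype(np.int64).ravel(), minlength=256).astype(float)
    if hist.size > 256:
        raise ValueError("grayscale values must lie in [0, 255]")
    n = hist.sum()
    w0 = np.cumsum(hist)  # pixels at level <= T
    w1 = n - w0
    mu0 = np.cumsum(hist * np.arange(256))
    mu_total = mu0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_total - mu0) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)
    return int(np.argmax(var_between))


def binarise(gray: np.ndarray) -> np.ndarray:
    """Binarise a grayscale raster with Otsu's threshold (1 iff > T).

    A constant raster has no separable foreground: the result is an
    all-zero mask and a :class:`SegmentationWarning` is emitted.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    if gray.min() == gray.max():
        warnings.warn(
            "constant image: no foreground separable", SegmentationWarning, stacklevel=2
        )
        return np.zeros(gray.shape, dtype=bool)
    return gray > otsu_threshold(gray)


def filter_blobs(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 0 or not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False  # background
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the raster border."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(mask)


def count_area(mask: np.ndarray) -> int:
    """Silhouette area: the number of foreground pixels."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def process_frame(
    frame: np.ndarray, config: SegmentationConfig, frame_index: int = 0
) -> FrameResult:
    """Run the full area-detection pipeline on one RGB frame.

    Degenerate frames (nothing left after filtering) yield area 0 with a
    warning code rather than an error, so long recordings survive bad
    frames. Warning codes: ``constant_roi`` (no contrast left after
    background suppression), ``polarity_inverted`` (binarisation put the
    majority of the ROI in the foreground and was flipped), ``no_blobs``
    (no component survived).
    """
    codes: list[str] = []
    roi_frame = crop_roi(frame, config.roi) if config.roi is not None else _validate_frame(frame)

    lab = rgb_to_lab(roi_frame)
    garment = threshold_mask(lab, config.garment_threshold)
    repainted = replace_pixels(roi_frame, garment, config.replacement_rgb)

    lstar = normalize_lightness(rgb_to_lab(repainted))
    keep = water_mask(lstar, config.water_lstar_range)
    keep = waterline_filter(keep, config.waterline_row - 1)  # 1-based -> 0-based

    # Suppress removed pixels to black so water is the dark class.
    gray = rgb_to_gray(repainted)
    gray = np.where(keep, gray, 0).astype(np.uint8)

    if gray.min() == gray.max():
        codes.append("constant_roi")
        bw = np.zeros(gray.shape, dtype=bool)
    else:
        bw = gray > otsu_threshold(gray)
        if np.count_nonzero(bw) > 0.5 * bw.size:
            codes.append("polarity_inverted")
            bw = ~bw & keep

    bw = filter_blobs(bw, config.min_blob_area)
    bw = fill_holes(bw)
    area = count_area(bw)
    if area == 0 and "constant_roi" not in codes:
        codes.append("no_blobs")
    return FrameResult(
        area_pixels=area, final_mask=bw, frame_index=frame_index, warnings=codes
    )
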