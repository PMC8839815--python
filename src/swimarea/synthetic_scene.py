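"""Parametric pool-scene renderer with exact ground-truth silhouettes.

The renderer emulates the elements an underwater tethered-swimming
frame confronts the pipeline with: a bluish-green water background,
bright lane-rope stripes, a water line with a mirrored (attenuated)
reflection of the swimmer above it, and a swimmer built from
skin-coloured, dark-red (swimwear) and dark (cap) regions. Per-pixel
Gaussian noise adds minimal sensor realism.

Default colours are chosen so that each region lands on the intended
side of the shipped frontal thresholds: the swimwear and cap fall
inside the garment CIELAB box (and are repainted), the skin and the
chest replacement colour fall inside the L* keep interval, and the
water and lane colours fall outside it. The ground truth is the exact
set of rasterised silhouette pixels, so end-to-end area accuracy can be
scored without real footage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from skimage import draw

__all__ = [
    "SwimmerShape",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_sequence",
]

# Defaults (RGB). See module docstring for how each relates to the
# shipped segmentation thresholds.
WATER_RGB = (0, 215, 170)
LANE_RGB = (230, 200, 40)
SKIN_RGB = (180, 130, 100)
SWIMWEAR_RGB = (80, 62, 60)
CAP_RGB = (70, 70, 70)

#: Reflection blending: reflected pixel = (1-w)·part colour + w·water.
REFLECTION_ATTENUATION = 0.3


@dataclass(frozen=True)
class SwimmerShape:
    """Front-view swimmer silhouette: torso ellipse, head disc, two arms.

    Lengths are in pixels; ``arm_angle_deg`` is measured from horizontal,
    arms extending upward-outward from the shoulders.
    """

    torso_center: Tuple[float, float] = (170.0, 160.0)  # (row, col)
    torso_axes: Tuple[float, float] = (34.0, 54.0)  # (semi-rows, semi-cols)
    head_radius: float = 16.0
    arm_length: float = 40.0
    arm_width: float = 12.0
    arm_angle_deg: float = 40.0


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic pool scene."""

    frame_height: int = 240
    frame_width: int = 320
    water_rgb: Tuple[int, int, int] = WATER_RGB
    lane_rgb: Tuple[int, int, int] = LANE_RGB
    skin_rgb: Tuple[int, int, int] = SKIN_RGB
    swimwear_rgb: Tuple[int, int, int] = SWIMWEAR_RGB
    cap_rgb: Tuple[int, int, int] = CAP_RGB
    waterline_row: int = 97  # 1-based, matching SegmentationConfig
    swimmer: SwimmerShape | None = field(default_factory=SwimmerShape)
    reflection_enabled: bool = True
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("water_rgb", "lane_rgb", "skin_rgb", "swimwear_rgb", "cap_rgb"):
            if any(not 0 <= c <= 255 for c in getattr(self, name)):
                raise ValueError(f"{name} channels must lie in [0, 255]")


@dataclass
class GroundTruth:
    """Exact silhouette mask and its pixel count (reflection excluded)."""

    silhouette_mask: np.ndarray
    area_pixels: int


def _swimmer_region_masks(
    shape: SwimmerShape, height: int, width: int, scale: float
) -> dict[str, np.ndarray]:
    """Rasterise the swimmer into skin / swimwear / cap part masks.

    ``scale`` multiplies every length about the torso centre, so the
    silhouette area scales as scale².
    """
    cr, cc = shape.torso_center
    ar = shape.torso_axes[0] * scale
    ac = shape.torso_axes[1] * scale
    head_r = shape.head_radius * scale

    def blank() -> np.ndarray:
        return np.zeros((height, width), dtype=bool)

    torso = blank()
    rr, cc_ = draw.ellipse(cr, cc, ar, ac, shape=(height, width))
    torso[rr, cc_] = True

    head = blank()
    head_center_row = cr - ar - 0.85 * head_r
    if head_r > 0:
        rr, cc_ = draw.disk((head_center_row, cc), head_r, shape=(height, width))
        head[rr, cc_] = True

    arms = blank()
    theta = np.deg2rad(shape.arm_angle_deg)
    half_w = shape.arm_width * scale / 2.0
    length = shape.arm_length * scale
    shoulder_row = cr - 0.25 * ar
    sides = (-1.0, 1.0) if length > 0 and half_w > 0 else ()
    for side in sides:
        r0, c0 = shoulder_row, cc + side * 0.9 * ac
        r1 = r0 - length * np.sin(theta)
        c1 = c0 + side * length * np.cos(theta)
        # rectangle as a polygon: offset the axis by the half-width normal
        nr, nc = np.cos(theta), side * np.sin(theta)
        poly_r = [r0 - half_w * nr, r0 + half_w * nr, r1 + half_w * nr, r1 - half_w * nr]
        poly_c = [c0 + half_w * nc, c0 - half_w * nc, c1 - half_w * nc, c1 + half_w * nc]
        rr, cc_ = draw.polygon(poly_r, poly_c, shape=(height, width))
        arms[rr, cc_] = True

    silhouette = torso | head | arms
    cap = head & (np.arange(height)[:, None] < head_center_row)
    band_top = cr + 0.15 * ar
    band_bottom = cr + 0.80 * ar
    rows = np.arange(height)[:, None]
    swimwear = torso & (rows >= band_top) & (rows <= band_bottom)
    skin = silhouette & ~cap & ~swimwear
    return {"silhouette": silhouette, "skin": skin, "swimwear": swimwear, "cap": cap}


def _check_silhouette_bounds(
    shape: SwimmerShape, spec: SceneSpec, scale: float
) -> None:
    """Analytic bound check: the silhouette must fit the frame (and stay
    below the water line when a reflection is drawn)."""
    cr, cc = shape.torso_center
    ar = shape.torso_axes[0] * scale
    ac = shape.torso_axes[1] * scale
    head_r = shape.head_radius * scale
    length = shape.arm_length * scale
    theta = np.deg2rad(shape.arm_angle_deg)
    top = min(cr - ar - 0.85 * head_r - head_r, cr - 0.25 * ar - length * np.sin(theta))
    bottom = cr + ar
    left = min(cc - ac, cc - 0.9 * ac - length * np.cos(theta) - shape.arm_width)
    right = 2 * cc - left
    if top < 0 or bottom >= spec.frame_height or left < 0 or right >= spec.frame_width:
        raise ValueError("silhouette exceeds the frame bounds")
    if spec.reflection_enabled and top < spec.waterline_row - 1:
        raise ValueError(
            "silhouette crosses the water line while a reflection is drawn"
        )


def render_scene(spec: SceneSpec, scale: float = 1.0) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a fixed spec (seed included).

    Returns the RGB frame (uint8) and the exact ground truth. The
    reflection, when enabled, is the vertical mirror of the silhouette
    about the water line, blended toward the water colour; it is not
    part of the ground truth.
    """
    h, w = spec.frame_height, spec.frame_width
    frame = np.empty((h, w, 3), dtype=float)
    frame[:] = spec.water_rgb

    # lane-rope stripes: vertical bands behind the swimmer
    stripe_w = max(3, w // 50)
    for frac in (0.12, 0.88):
        c0 = int(frac * w) - stripe_w // 2
        frame[:, max(c0, 0) : min(c0 + stripe_w, w)] = spec.lane_rgb

    if spec.swimmer is None:
        silhouette = np.zeros((h, w), dtype=bool)
    else:
        _check_silhouette_bounds(spec.swimmer, spec, scale)
        parts = _swimmer_region_masks(spec.swimmer, h, w, scale)
        silhouette = parts["silhouette"]

        part_colours = {
            "skin": spec.skin_rgb,
            "swimwear": spec.swimwear_rgb,
            "cap": spec.cap_rgb,
        }
        if spec.reflection_enabled:
            wl0 = spec.waterline_row - 1  # first kept (underwater) row
            water = np.asarray(spec.water_rgb, dtype=float)
            for name, colour in part_colours.items():
                rows, cols = np.nonzero(parts[name])
                refl_rows = 2 * wl0 - 1 - rows
                ok = (refl_rows >= 0) & (refl_rows < h)
                blended = (1 - REFLECTION_ATTENUATION) * np.asarray(
                    colour, dtype=float
                ) + REFLECTION_ATTENUATION * water
                frame[refl_rows[ok], cols[ok]] = blended

        for name, colour in part_colours.items():
            frame[parts[name]] = colour

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)

    frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        silhouette_mask=silhouette, area_pixels=int(np.count_nonzero(silhouette))
    )
    return frame, truth


def render_sequence(
    spec: SceneSpec,
    n_frames: int,
    osc_freq_hz: float,
    osc_amplitude: float,
    fs_hz: float = 30.0,
    osc_phase_rad: float = 0.0,
) -> List[tuple[np.ndarray, GroundTruth]]:
    """Render frames whose silhouette area oscillates sinusoidally.

    The silhouette's linear scale at time t is sqrt(1 + A·sin(2πft+φ)),
    so the ground-truth area follows 1 + A·sin(2πft+φ) times the base
    area, emulating the periodic area fluctuation of the stroke cycle.
    ``osc_phase_rad`` shifts the oscillation, e.g. to emulate cameras
    whose area fluctuations peak at different stroke phases.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= osc_amplitude < 1:
        raise ValueError("osc_amplitude must lie in [0, 1)")
    if osc_freq_hz >= fs_hz / 2:
        raise ValueError(
            f"osc_freq_hz {osc_freq_hz} aliases at sampling rate {fs_hz}"
        )
    out = []
    for i in range(n_frames):
        t = i / fs_hz
        area_scale = 1.0 + osc_amplitude * np.sin(
            2 * np.pi * osc_freq_hz * t + osc_phase_rad
        )
        # frame 0 keeps the spec's own seed, so a 1-frame sequence
        # reproduces render_scene exactly
        frame_spec = replace(spec, seed=(spec.seed + i * 1000003) % (2**31))
        out.append(render_scene(frame_spec, scale=float(np.sqrt(area_scale))))
    return out
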