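import numpy as np
import pytest

from swimarea.segmentation import frontal_config
from swimarea.synthetic_scene import SceneSpec, SwimmerShape, render_scene


@pytest.fixture
def config():
    return frontal_config()


@pytest.fixture
def scene():
    """One default noisy pool scene with its exact ground truth."""
    return render_scene(SceneSpec(seed=3))


@pytest.fixture
def small_swimmer():
    """A swimmer small enough to fit entirely above the water line."""
    return SwimmerShape(
        torso_center=(60.0, 160.0),
        torso_axes=(20.0, 35.0),
        head_radius=10.0,
        arm_length=25.0,
        arm_width=8.0,
    )


def brute_force_otsu(gray: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class-variance search.

    Evaluates every candidate threshold T in 0..255 with a direct
    two-class split and returns the lowest argmax.
    """
    vals = gray.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            v = 0.0
        else:
            w0 = lo.size / vals.size
            w1 = hi.size / vals.size
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[int]:
    """Independent oracle: 8-connected component areas by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            n = 0
            while stack:
                r, c = stack.pop()
                n += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            areas.append(n)
    return areas
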