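"""Analyses of per-frame area series and the steady-state drag model.

An :class:`AreaSeries` holds the silhouette area (pixels) per frame at a
nominal sampling rate (30 Hz for the target cameras). The analyses are:

* ordinary least-squares regression between two area series (e.g.
  frontal vs lateral camera), reported with the coefficient of
  determination R²;
* a single-sided magnitude spectrum of the mean-removed series, from
  which the dominant stroke-cycle frequency is read off. The estimator
  uses a rectangular window with zero padding (default factor 8), so
  peak locations are resolved well below the raw 1/T bin width;
* the quadratic resistive-force model F_R = ½ C_R A ρ v² and the
  Newtonian force balance m·a = F_P + F_R, with F_R entered as a signed
  quantity (negative when opposing forward motion), so constant speed
  corresponds literally to F_P = −F_R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AreaSeries",
    "RegressionResult",
    "Spectrum",
    "DragParams",
    "ForceBalance",
    "AnalysisWarning",
    "linear_fit",
    "compute_spectrum",
    "dominant_frequency",
    "resistive_force",
    "pixels_to_m2",
    "net_force_acceleration",
]


class AnalysisWarning(UserWarning):
    """Degenerate but survivable analysis conditions."""


@dataclass
class AreaSeries:
    """Uniformly sampled area-vs-time record from one camera."""

    times_s: np.ndarray
    areas: np.ndarray
    sampling_rate_hz: float
    camera_label: str = "frontal"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times_s.shape != self.areas.shape or self.times_s.ndim != 1:
            raise ValueError("times and areas must be 1-D arrays of equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    @classmethod
    def from_areas(
        cls, areas: np.ndarray, sampling_rate_hz: float = 30.0, camera_label: str = "frontal"
    ) -> "AreaSeries":
        """Build a series with times i / fs from a bare area vector."""
        areas = np.asarray(areas, dtype=float)
        times = np.arange(len(areas)) / sampling_rate_hz
        return cls(times, areas, sampling_rate_hz, camera_label)

    def __len__(self) -> int:
        return len(self.areas)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class Spectrum:
    """Single-sided magnitude spectrum; frequencies ascend from 0 to Nyquist."""

    frequencies_hz: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies_hz.shape != self.magnitudes.shape:
            raise ValueError("frequencies and magnitudes must have equal length")


@dataclass
class DragParams:
    """Resistive-force model parameters.

    c_r is the dimensionless drag coefficient (obtained externally, e.g.
    from a velocity-perturbation protocol); rho the water density in
    kg/m³; pixel_scale_mm2 the optional image-to-world area scale.
    """

    c_r: float
    rho: float = 1000.0
    pixel_scale_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.pixel_scale_mm2 is not None and self.pixel_scale_mm2 <= 0:
            raise ValueError("pixel_scale_mm2 must be > 0 when present")


@dataclass
class ForceBalance:
    """Newtonian balance m·a = F_P + F_R with signed forces in newtons."""

    mass_kg: float
    f_p: float
    f_r: float
    acceleration: float = field(init=False)

    def __post_init__(self) -> None:
        self.acceleration = net_force_acceleration(self.mass_kg, self.f_p, self.f_r)


def linear_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x; R² is the squared Pearson r.

    A constant predictor is an error; a constant response yields a flat
    fit with R² = 0 and an :class:`AnalysisWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant: R^2 defined as 0", AnalysisWarning, stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def compute_spectrum(series: AreaSeries, zero_pad_factor: int = 8) -> Spectrum:
    """Single-sided DFT magnitude spectrum of the mean-removed series.

    Rectangular window; the series is zero-padded to ``zero_pad_factor``
    times its length so that spectral peaks are interpolated onto a
    finer frequency grid. Magnitudes are raw DFT magnitudes |X_k|.
    """
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    n = len(series)
    if n < 8:
        raise ValueError("need at least 8 samples")
    dt = np.diff(series.times_s)
    nominal = 1.0 / series.sampling_rate_hz
    if np.max(np.abs(dt - nominal)) > 0.01 * nominal:
        raise ValueError("sampling is not uniform at the stated rate")
    x = series.areas - series.areas.mean()
    nfft = n * zero_pad_factor
    mags = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, d=nominal)
    return Spectrum(frequencies_hz=freqs, magnitudes=mags)


def dominant_frequency(spec: Spectrum, min_hz: float = 0.1) -> tuple[float, float]:
    """Frequency and magnitude of the largest spectral peak >= min_hz.

    The near-DC band below ``min_hz`` is excluded (residual mean
    leakage); ties break toward the lower frequency.
    """
    if min_hz < 0:
        raise ValueError("min_hz must be >= 0")
    if len(spec.frequencies_hz) == 0:
        raise ValueError("empty spectrum")
    sel = spec.frequencies_hz >= min_hz
    if not sel.any():
        raise ValueError(f"no spectral bins at or above {min_hz} Hz")
    mags = spec.magnitudes[sel]
    if np.all(mags == 0):
        raise ValueError("no periodicity: all magnitudes are zero")
    idx = int(np.argmax(mags))  # argmax returns the first (lowest-f) maximiser
    freqs = spec.frequencies_hz[sel]
    return float(freqs[idx]), float(mags[idx])


def resistive_force(params: DragParams, area_m2: float, velocity_mps: float) -> float:
    """Steady-state resistive force F_R = ½ C_R A ρ v², in newtons."""
    if area_m2 < 0:
        raise ValueError("area must be >= 0")
    return 0.5 * params.c_r * area_m2 * params.rho * velocity_mps**2


def pixels_to_m2(area_pixels: int, pixel_scale_mm2: float) -> float:
    """Convert a pixel count to m² given the per-pixel area in mm²."""
    if pixel_scale_mm2 <= 0:
        raise ValueError("pixel_scale_mm2 must be > 0")
    return area_pixels * pixel_scale_mm2 * 1e-6


def net_force_acceleration(mass_kg: float, f_p: float, f_r: float) -> float:
    """Acceleration (m/s²) from signed propulsive and resistive forces."""
    if mass_kg <= 0:
        raise ValueError("mass must be > 0")
    return (f_p + f_r) / mass_kg
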