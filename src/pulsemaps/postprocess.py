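"""Map postprocessing: decibel conversion, normalization, quantization, display.

Maps carry wildly different value ranges (bounded ratios vs. unbounded
powers), so before comparison or histogramming they are (optionally)
converted to decibels,

    V(I) = U * log10(|I| + eps)   with U in {10, 20},

normalized to [0, 1] over all pixels of a map, and discretized to
``N_scale`` (default 256) levels.  Display rendering uses a separate,
manually chosen window (lo, hi) clipped and mapped linearly to 8 bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .features import FeatureMap

__all__ = [
    "VisualizationConfig",
    "DB_POLICY",
    "db_convert",
    "apply_db_policy",
    "normalize_map",
    "quantize_map",
    "display_window",
    "save_display_image",
]

#: dB factor per feature: power-like quantities get U=10, amplitude-like
#: U=20; bounded/ratio/frequency/phase maps stay linear (None).
DB_POLICY: dict[str, int | None] = {
    "mean_intensity": None,
    "band_power": 10,
    "band_mean_power": 10,
    "band_max_over_band_power": None,
    "spectral_centroid": None,
    "spectral_spread": None,
    "spectral_skewness": None,
    "spectral_kurtosis": None,
    "spectral_crest": None,
    "spectral_flatness": None,
    "spectral_entropy": None,
    "spectral_slope": None,
    "max_frequency": None,
    "phasor_phase": None,
    "phasor_amp": 20,
    "temporal_var": 10,
    "spectral_flux_pos": 10,
    "spectral_flux_neg": 10,
    "ratio_flux_pos": None,
    "ratio_flux_neg": None,
}


@dataclass(frozen=True)
class VisualizationConfig:
    """Postprocessing parameters (dB stabilizer, quantization, display window)."""

    epsilon: float = 1e-12
    n_scale: int = 256
    display_limits: "tuple[float, float] | None" = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_scale < 2:
            raise ValueError("need at least 2 quantization levels")
        if self.display_limits is not None and not self.display_limits[0] < self.display_limits[1]:
            raise ValueError("display limits must satisfy lo < hi")


def db_convert(fmap: FeatureMap, u: int, epsilon: float = 1e-12) -> FeatureMap:
    """Elementwise ``U * log10(|I| + eps)``; eps guards zero-valued pixels."""
    if u not in (10, 20):
        raise ValueError("dB factor must be 10 or 20")
    values = u * np.log10(np.abs(fmap.values) + epsilon)
    return FeatureMap(values=values, feature_id=fmap.feature_id, t0=fmap.t0, db_scaled=True)


def apply_db_policy(
    bank: dict[str, FeatureMap], epsilon: float = 1e-12
) -> dict[str, FeatureMap]:
    """Convert the power/amplitude-like maps of a bank to dB, per :data:`DB_POLICY`."""
    out = {}
    for fid, fmap in bank.items():
        u = DB_POLICY.get(fid)
        out[fid] = db_convert(fmap, u, epsilon) if u is not None else fmap
    return out


def normalize_map(fmap: FeatureMap) -> FeatureMap:
    """Min-max normalize to [0, 1] over all pixels; a constant map maps to zeros."""
    v = np.asarray(fmap.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite pixels")
    lo, hi = v.min(), v.max()
    norm = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return FeatureMap(values=norm, feature_id=fmap.feature_id, t0=fmap.t0, db_scaled=fmap.db_scaled)


def quantize_map(fmap: FeatureMap, n_scale: int = 256) -> np.ndarray:
    """Discretize a [0, 1] map to integer levels 0 .. n_scale-1."""
    v = np.asarray(fmap.values, dtype=float)
    if v.min() < 0 or v.max() > 1:
        raise ValueError("map must be normalized to [0, 1] before quantization")
    return np.minimum(np.floor(v * n_scale), n_scale - 1).astype(np.int32)


def display_window(fmap: FeatureMap, limits: tuple[float, float]) -> np.ndarray:
    """Render an 8-bit display image with manual window limits.

    Linear gray-scale transform of [lo, hi] onto [0, 255]; values outside the
    window clip to its ends.  Half-integer codes round half up (0.5 -> 128).
    """
    lo, hi = limits
    if not lo < hi:
        raise ValueError("window limits must satisfy lo < hi")
    v = np.clip(np.asarray(fmap.values, dtype=float), lo, hi)
    scaled = (v - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def save_display_image(fmap: FeatureMap, limits: tuple[float, float], path: str | Path) -> Path:
    """Render with :func:`display_window` and save as 8-bit PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError("display images are exported as PNG or TIFF")
    iio.imwrite(path, display_window(fmap, limits))
    return path
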