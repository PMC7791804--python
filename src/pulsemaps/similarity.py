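"""Histogram-intersection similarity maps against a background model.

A normalized model histogram H_M is built from a large, representative
background region of a quantized map.  For every pixel, the histogram H_P of
the ``N_kernel_hist x N_kernel_hist`` patch centred on it (boundaries by
symmetric reflection) is intersected with the model,

    eta(H_M, H_P) = sum_j min(H_M[j], H_P[j])  in [0, 1],

yielding a similarity map: high where the patch looks like background noise,
low over pulsatile structure.  The per-pixel computation below is the naive
reference semantics (an integral-histogram acceleration would be possible
but is not needed at the lattice sizes this package targets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "SimilarityConfig",
    "model_histogram",
    "histogram_intersection",
    "similarity_map",
]


@dataclass
class Histogram:
    """Normalized bin-mass vector over quantization levels."""

    masses: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1:
            raise ValueError("histogram must be a 1-D mass vector")
        if np.any(self.masses < 0):
            raise ValueError("bin masses must be nonnegative")
        if not np.isclose(self.masses.sum(), 1.0, atol=1e-9):
            raise ValueError("histogram must be normalized to unit mass")

    @property
    def n_bins(self) -> int:
        return self.masses.shape[0]


@dataclass(frozen=True)
class SimilarityConfig:
    """Patch-histogram parameters (bins, odd patch side, boundary mode)."""

    n_bins: int = 256
    n_kernel_hist: int = 31
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.n_kernel_hist < 1 or self.n_kernel_hist % 2 == 0:
            raise ValueError("patch side must be odd and >= 1")
        if self.padding != "symmetric":
            raise ValueError("only symmetric padding is supported")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")


def model_histogram(qmap: np.ndarray, region_mask: np.ndarray, n_bins: int = 256) -> Histogram:
    """Normalized histogram of quantized levels inside a region."""
    qmap = np.asarray(qmap)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != qmap.shape:
        raise ValueError("region mask must match the map shape")
    levels = qmap[region_mask]
    if levels.size == 0:
        raise ValueError("empty model region")
    if levels.min() < 0 or levels.max() >= n_bins:
        raise ValueError("quantized levels outside [0, n_bins)")
    counts = np.bincount(levels.ravel(), minlength=n_bins).astype(float)
    return Histogram(masses=counts / counts.sum())


def histogram_intersection(h_m: Histogram, h_p: Histogram) -> float:
    """eta = sum_j min(H_M[j], H_P[j]); 1 for identical normalized histograms."""
    if h_m.n_bins != h_p.n_bins:
        raise ValueError("histograms must share the bin count")
    return float(np.minimum(h_m.masses, h_p.masses).sum())


def similarity_map(
    qmap: np.ndarray, h_m: Histogram, cfg: SimilarityConfig | None = None
) -> np.ndarray:
    """Per-pixel histogram intersection between patch histograms and the model.

    ``qmap`` must be quantized to ``cfg.n_bins`` levels.  Each pixel's patch
    is the ``n_kernel_hist``-sided block centred on it; boundary pixels use
    symmetric reflection.  The patch side may not exceed twice the smaller
    map dimension (the reflection would run out of pixels).
    """
    cfg = cfg or SimilarityConfig()
    qmap = np.asarray(qmap)
    if qmap.ndim != 2:
        raise ValueError("expected a 2-D quantized map")
    if h_m.n_bins != cfg.n_bins:
        raise ValueError("model histogram bin count must match the config")
    if qmap.min() < 0 or qmap.max() >= cfg.n_bins:
        raise ValueError("map not quantized to the configured level count")
    r = cfg.n_kernel_hist // 2
    if r > min(qmap.shape):
        raise ValueError("patch larger than the map allows with symmetric padding")
    padded = np.pad(qmap, r, mode="symmetric")
    rows, cols = qmap.shape
    out = np.empty((rows, cols), dtype=float)
    side = cfg.n_kernel_hist
    model = h_m.masses
    inv_patch = 1.0 / (side * side)
    for i in range(rows):
        for j in range(cols):
            patch = padded[i : i + side, j : j + side]
            counts = np.bincount(patch.ravel(), minlength=cfg.n_bins)
            out[i, j] = np.minimum(model, counts * inv_patch).sum()
    return out
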