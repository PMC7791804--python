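"""ROI generation: Gaussian spatial pooling and decimation to the ROI lattice.

Every output lattice pixel is a Gaussian-weighted average of an
``N_kernel x N_kernel`` neighbourhood of the input frame ("blurring image
patches"), after which the frame is decimated so that each kept pixel
represents one ROI.  Convolution is *valid* (no border padding): the lattice
covers only neighbourhoods fully inside the frame, which is what reproduces
the published map resolutions (e.g. (1920-41+1)/5 = 376 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PoolingConfig",
    "gaussian_kernel_1d",
    "gaussian_pool",
    "decimate",
    "pool_and_decimate",
    "lattice_shape",
]


@dataclass(frozen=True)
class PoolingConfig:
    """Spatial pooling / decimation parameters.

    sigma_gauss : Gaussian standard deviation [pix]
    n_kernel    : odd kernel side length [pix]
    d_x, d_y    : column/row decimation factors
    center      : anchor the decimation grid at patch centers
    """

    sigma_gauss: float
    n_kernel: int
    d_x: int = 1
    d_y: int = 1
    center: bool = True

    def __post_init__(self) -> None:
        if self.n_kernel < 1 or self.n_kernel % 2 == 0:
            raise ValueError("kernel side must be odd and >= 1")
        if self.d_x < 1 or self.d_y < 1:
            raise ValueError("decimation factors must be >= 1")
        if self.sigma_gauss <= 0:
            raise ValueError("sigma_gauss must be positive")


def gaussian_kernel_1d(sigma: float, n: int) -> np.ndarray:
    """Sampled 1-D Gaussian of length ``n``, renormalized to unit sum."""
    x = np.arange(n, dtype=float) - (n - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_pool(frames: np.ndarray, cfg: PoolingConfig) -> np.ndarray:
    """Valid separable Gaussian convolution of a frame or frame stack.

    Accepts a 2-D frame or a ``(n, rows, cols)`` stack; the spatial output
    dims are ``rows - n_kernel + 1`` by ``cols - n_kernel + 1``.  The kernel
    (outer product of sampled 1-D Gaussians) sums to one, so constant regions
    are preserved.
    """
    frames = np.asarray(frames, dtype=float)
    squeeze = frames.ndim == 2
    if squeeze:
        frames = frames[None]
    n = cfg.n_kernel
    if frames.shape[1] < n or frames.shape[2] < n:
        raise ValueError("frame smaller than pooling kernel")
    k = gaussian_kernel_1d(cfg.sigma_gauss, n)
    # same-size separable convolution, then crop margins -> exact valid result
    out = ndimage.convolve1d(frames, k, axis=1, mode="constant")
    out = ndimage.convolve1d(out, k, axis=2, mode="constant")
    r = (n - 1) // 2
    out = out[:, r : frames.shape[1] - r, r : frames.shape[2] - r]
    return out[0] if squeeze else out


def _phase(d: int, center: bool) -> int:
    return (d - 1) // 2 if center else 0


def decimate(frames: np.ndarray, cfg: PoolingConfig) -> np.ndarray:
    """Keep every d_x-th column / d_y-th row of a frame or stack.

    With ``center`` the first kept index is the patch-center offset
    ``floor((d - 1) / 2)``.
    """
    frames = np.asarray(frames)
    py, px = _phase(cfg.d_y, cfg.center), _phase(cfg.d_x, cfg.center)
    return frames[..., py :: cfg.d_y, px :: cfg.d_x]


def pool_and_decimate(frames: np.ndarray, cfg: PoolingConfig) -> np.ndarray:
    """Full ROI-generation stage: valid Gaussian pooling then decimation."""
    return decimate(gaussian_pool(frames, cfg), cfg)


def lattice_shape(frame_shape: tuple[int, int], cfg: PoolingConfig) -> tuple[int, int]:
    """ROI-lattice dims produced by :func:`pool_and_decimate` for a frame shape."""
    rows, cols = frame_shape
    vr, vc = rows - cfg.n_kernel + 1, cols - cfg.n_kernel + 1
    if vr < 1 or vc < 1:
        raise ValueError("frame smaller than pooling kernel")
    py, px = _phase(cfg.d_y, cfg.center), _phase(cfg.d_x, cfg.center)
    return ((vr - py - 1) // cfg.d_y + 1, (vc - px - 1) // cfg.d_x + 1)
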