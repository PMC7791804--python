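"""Synthetic vital-sign video scenes with known ground truth.

Real PPGI/IRT recordings of subjects are not redistributable, so this module
generates deterministic stand-in clips with the statistical structure the
analysis chain assumes: a static noisy background, a pulsatile foreground
(a filled silhouette for PPGI-like clips, a thin contour ring for IRT-like
clips), and optional confounders observed in practice — an "eyes" sub-region
oscillating at its own frequency, a specular reflection carrying a scaled
copy of the pulse, multiplicative illumination flicker, and a slowly
ramping cast-shadow region.

Defaults describe one fixed study condition: 25 Hz, 10 s clips, a 1.5 Hz
(90 bpm) pulse of amplitude 3 intensity units against unit-SD Gaussian
noise on a baseline of 100.  Ground-truth masks are delivered on the ROI
lattice: a lattice pixel counts as foreground when its Gaussian-pooled
modulation weight is >= 90% of the maximum (i.e. its pooling support is
essentially pure foreground) and as background when that weight is <= 1%
and no other dynamic region reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .roi import PoolingConfig, pool_and_decimate
from .video_io import FrameSequence

__all__ = ["SceneConfig", "SceneGroundTruth", "generate_scene", "scene_ground_truth",
           "silhouette_mask", "contour_mask"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene (all intensities in raw camera units)."""

    rows: int = 140
    cols: int = 180
    fs: float = 25.0
    duration: float = 10.0
    baseline: float = 100.0
    pulse_freq: float = 1.5
    pulse_amp: float = 3.0
    pulse_phase: float = 0.0
    modulation_mode: str = "silhouette"  # 'silhouette' (PPGI-like) or 'contour' (IRT-like)
    ellipse_axes: tuple[float, float] = (0.33, 0.22)  # semi-axes as fractions of rows/cols
    amp_texture: float = 0.3  # relative SD of the smooth amplitude field over the subject
    noise_sd: float = 1.0
    noise_ar: float = 0.0  # AR(1) coefficient for temporally correlated sensor noise
    eyes: bool = False
    eyes_freq: float = 3.2
    eyes_amp: float | None = None
    reflection_gain: float = 0.0
    flicker_freq: float = 0.0
    flicker_amp: float = 0.0
    shadow_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pulse_freq < self.fs / 2:
            raise ValueError("pulse frequency must lie below Nyquist")
        if self.pulse_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be nonnegative")
        if self.modulation_mode not in ("silhouette", "contour"):
            raise ValueError("modulation_mode must be 'silhouette' or 'contour'")
        if not 0 <= self.noise_ar < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.rows < 8 or self.cols < 8:
            raise ValueError("scene too small")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs))


def silhouette_mask(cfg: SceneConfig) -> np.ndarray:
    """Filled elliptic subject silhouette, centred in the frame."""
    ry = cfg.ellipse_axes[0] * cfg.rows
    rx = cfg.ellipse_axes[1] * cfg.cols
    y, x = np.ogrid[: cfg.rows, : cfg.cols]
    cy, cx = (cfg.rows - 1) / 2.0, (cfg.cols - 1) / 2.0
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def contour_mask(cfg: SceneConfig) -> np.ndarray:
    """Two-pixel contour ring of the silhouette (IRT emphasizes contours)."""
    sil = silhouette_mask(cfg)
    return sil & ~ndimage.binary_erosion(sil, iterations=2)


def _eyes_mask(cfg: SceneConfig) -> np.ndarray:
    """Two small disks in the upper half of the silhouette."""
    r = max(2.0, 0.035 * cfg.rows)
    cy = (cfg.rows - 1) / 2.0 - 0.15 * cfg.rows
    cx = (cfg.cols - 1) / 2.0
    dx = 0.09 * cfg.cols
    y, x = np.ogrid[: cfg.rows, : cfg.cols]
    left = (y - cy) ** 2 + (x - (cx - dx)) ** 2 <= r**2
    right = (y - cy) ** 2 + (x - (cx + dx)) ** 2 <= r**2
    return left | right


def _reflection_mask(cfg: SceneConfig) -> np.ndarray:
    """Small off-body patch (e.g. a glossy surface mirroring the subject)."""
    ry, rx = 0.06 * cfg.rows, 0.05 * cfg.cols
    cy, cx = 0.82 * cfg.rows, 0.85 * cfg.cols
    y, x = np.ogrid[: cfg.rows, : cfg.cols]
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _shadow_mask(cfg: SceneConfig) -> np.ndarray:
    """Vertical strip at the left frame edge (cast shadow of someone passing)."""
    mask = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    mask[:, : max(2, int(0.10 * cfg.cols))] = True
    return mask


def _pulse_weight(cfg: SceneConfig) -> np.ndarray:
    w = (silhouette_mask(cfg) if cfg.modulation_mode == "silhouette" else contour_mask(cfg)).astype(
        float
    )
    if cfg.eyes:
        w[_eyes_mask(cfg)] = 0.0  # the eyes carry their own frequency instead
    return w


def _noise(cfg: SceneConfig, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if cfg.noise_ar == 0:
        return cfg.noise_sd * white
    a = cfg.noise_ar
    # stationary AR(1) with the requested marginal SD
    innov = cfg.noise_sd * np.sqrt(1 - a**2) * white
    return signal.lfilter([1.0], [1.0, -a], innov, axis=0)


def _amplitude_texture(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative amplitude field over the subject (mean 1).

    Real subjects never pulse with spatially uniform amplitude (perfusion,
    geometry and shading vary across the body), so the modulation weight is
    textured by a low-pass random field with relative SD ``amp_texture``,
    floored at 0.2 so every foreground pixel keeps a detectable pulse.
    """
    if cfg.amp_texture == 0:
        return np.ones((cfg.rows, cfg.cols))
    field = ndimage.gaussian_filter(
        rng.standard_normal((cfg.rows, cfg.cols)), sigma=0.05 * min(cfg.rows, cfg.cols)
    )
    sd = field.std()
    if sd > 0:
        field /= sd
    return np.clip(1.0 + cfg.amp_texture * field, 0.2, None)


def generate_scene(cfg: SceneConfig) -> FrameSequence:
    """Render the scene; bit-reproducible for a fixed seed."""
    n = cfg.n_frames
    t = np.arange(n) / cfg.fs
    rng = np.random.default_rng(cfg.seed)
    pulse = cfg.pulse_amp * np.sin(2 * np.pi * cfg.pulse_freq * t + cfg.pulse_phase)
    video = np.full((n, cfg.rows, cfg.cols), float(cfg.baseline))
    video += pulse[:, None, None] * (_pulse_weight(cfg) * _amplitude_texture(cfg, rng))[None]
    if cfg.eyes:
        amp = cfg.pulse_amp if cfg.eyes_amp is None else cfg.eyes_amp
        eyes_sig = amp * np.sin(2 * np.pi * cfg.eyes_freq * t)
        video += eyes_sig[:, None, None] * _eyes_mask(cfg)[None]
    if cfg.reflection_gain:
        video += (cfg.reflection_gain * pulse)[:, None, None] * _reflection_mask(cfg)[None]
    if cfg.shadow_amp:
        ramp = cfg.shadow_amp * (t / max(t[-1], 1e-9))
        video += ramp[:, None, None] * _shadow_mask(cfg)[None]
    if cfg.flicker_amp and cfg.flicker_freq:
        video *= (1.0 + cfg.flicker_amp * np.sin(2 * np.pi * cfg.flicker_freq * t))[:, None, None]
    video += _noise(cfg, rng, video.shape)
    return FrameSequence(
        frames=video, fs=cfg.fs, timestamps=t, bit_depth=16, modality="synthetic"
    )


@dataclass
class SceneGroundTruth:
    """Masks on the ROI lattice plus the per-region modulation frequencies [Hz]."""

    foreground: np.ndarray
    background: np.ndarray
    frequencies: dict[str, float]
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    #: bounding rectangle of the visible modulation extent — the kind of big
    #: manually boxed ROI_PULSE an operator would draw over the subject; it
    #: deliberately mixes pulsatile and boundary/background pixels
    pulse_region: np.ndarray | None = None


def _pooled_gain(mask: np.ndarray, pooling: PoolingConfig) -> np.ndarray:
    return pool_and_decimate(mask.astype(float), pooling)


def scene_ground_truth(cfg: SceneConfig, pooling: PoolingConfig) -> SceneGroundTruth:
    """Ground-truth foreground/background masks aligned to the ROI lattice.

    Foreground: pooled pulse-modulation weight >= 90% of its maximum (the
    pooling support is essentially pure foreground).  Background: every
    dynamic region's pooled weight <= 1% of that region's maximum.
    """
    g_pulse = _pooled_gain(_pulse_weight(cfg), pooling)
    gmax = g_pulse.max()
    if gmax <= 0:
        raise ValueError("scene has no pulsatile modulation")
    foreground = g_pulse >= 0.9 * gmax
    clean = g_pulse <= 0.01 * gmax
    # boxed evaluation ROI: rectangle hull of the visible modulation extent
    rr, cc = np.where(g_pulse >= 0.05 * gmax)
    pulse_region = np.zeros_like(foreground)
    pulse_region[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1] = True
    region_masks: dict[str, np.ndarray] = {}
    frequencies = {"pulse": cfg.pulse_freq}
    extras: list[tuple[str, np.ndarray, float]] = []
    if cfg.eyes:
        extras.append(("eyes", _eyes_mask(cfg), cfg.eyes_freq))
    if cfg.reflection_gain:
        extras.append(("reflection", _reflection_mask(cfg), cfg.pulse_freq))
    if cfg.shadow_amp:
        extras.append(("shadow", _shadow_mask(cfg), 0.0))
    for name, mask, freq in extras:
        g = _pooled_gain(mask, pooling)
        m = g.max()
        region_masks[name] = g >= 0.5 * m if m > 0 else np.zeros_like(g, dtype=bool)
        clean &= g <= 0.01 * max(m, 1e-12)
        foreground &= g <= 0.01 * max(m, 1e-12)
        frequencies[name] = freq
    return SceneGroundTruth(
        foreground=foreground,
        background=clean,
        frequencies=frequencies,
        region_masks=region_masks,
        pulse_region=pulse_region,
    )
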