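"""Temporal filtering: sliding windows, zero-phase bandpass, Hann taper.

Each ROI-lattice pixel is treated as a one-dimensional time series.  A
sliding window cuts the series into segments of ``N_seg`` samples; in each
segment the temporal mean is removed, a Butterworth bandpass restricted to
the anticipated heart-frequency band is applied forward-backward (zero phase
distortion, squared magnitude response), and a periodic Hann taper prepares
the segment for spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import signal

__all__ = [
    "FilterConfig",
    "design_bandpass",
    "filter_segment",
    "hann_window",
    "apply_window",
    "sliding_segments",
]


@dataclass(frozen=True)
class FilterConfig:
    """Bandpass / segmentation parameters.

    f_low, f_high : half-power (-3 dB) cutoff frequencies [Hz]
    order         : design order of the bandpass (even; applied
                    forward-backward, so the effective order doubles)
    t_seg         : segment length [s]
    zero_phase    : forward-backward application
    window        : taper applied before the FFT
    """

    f_low: float
    f_high: float
    order: int = 6
    t_seg: float = 10.0
    zero_phase: bool = True
    window: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")
        if self.order < 2 or self.order % 2:
            raise ValueError("design order must be even and >= 2")
        if self.t_seg <= 0:
            raise ValueError("segment length must be positive")

    def n_seg(self, fs: float) -> int:
        """Segment length in samples at rate ``fs``."""
        return int(round(self.t_seg * fs))


def design_bandpass(cfg: FilterConfig, fs: float) -> np.ndarray:
    """Design the recursive bandpass as second-order sections.

    The single-pass magnitude is -3 dB at ``f_low`` and ``f_high``
    (Butterworth half-power points); all poles lie inside the unit circle.
    """
    if cfg.f_high >= fs / 2:
        raise ValueError("upper cutoff must be below Nyquist")
    sos = signal.butter(
        cfg.order // 2, [cfg.f_low, cfg.f_high], btype="bandpass", fs=fs, output="sos"
    )
    return sos


def filter_segment(series: np.ndarray, sos: np.ndarray, zero_phase: bool = True) -> np.ndarray:
    """Mean-remove and bandpass one segment (time along axis 0).

    With ``zero_phase`` the filter runs forward-backward: no phase
    distortion, effective magnitude response squared.  Series much shorter
    than the filter's transient length are rejected.
    """
    series = np.asarray(series, dtype=float)
    order = 2 * sos.shape[0]  # single-pass filter order
    if series.shape[0] < 3 * order:
        raise ValueError("segment too short for reliable filtering")
    x = series - series.mean(axis=0, keepdims=True)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def hann_window(n: int) -> np.ndarray:
    """Periodic Hann taper of length ``n`` (sum n/2, sum of squares 3n/8)."""
    return signal.get_window("hann", n, fftbins=True)


def apply_window(seg: np.ndarray, window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """Pointwise taper along axis 0; returns (windowed segment, taper).

    The taper itself is returned because its coefficient sums are needed for
    power-spectrum scaling.
    """
    if window != "hann":
        raise ValueError(f"unsupported window {window!r}")
    seg = np.asarray(seg, dtype=float)
    w = hann_window(seg.shape[0])
    shape = (-1,) + (1,) * (seg.ndim - 1)
    return seg * w.reshape(shape), w


def sliding_segments(
    stack: np.ndarray, n_seg: int, hop: int = 1
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(start_index, segment_view)`` for a sliding window over a stack.

    ``stack`` has time on axis 0.  Consecutive segments overlap by
    ``n_seg - hop`` samples.  Views into the input are yielded, so memory
    stays bounded by the input plus one segment of derived data.
    """
    stack = np.asarray(stack)
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if stack.shape[0] < n_seg:
        raise ValueError("clip shorter than one segment")
    for start in range(0, stack.shape[0] - n_seg + 1, hop):
        yield start, stack[start : start + n_seg]
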