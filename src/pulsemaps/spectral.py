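"""Windowed, zero-padded segment spectra and analysis-band bin resolution.

Each windowed segment is zero-padded to ``N_FFT`` (a power of two) and
transformed; the single-sided power spectrum is scaled as

    P[k] = 2 |X[k]|^2 / (sum of window values)^2

so that the peak of a unit-amplitude in-band sinusoid reads A^2/2 = 0.5.
Because zero-padding oversamples the window's main lobe, *sums* of P over a
band overcount signal power by the equivalent noise bandwidth in bins,

    ENBW = N_FFT * sum(w^2) / (sum w)^2,

which is recorded on the spectrum so band-power features can report true
in-band power independently of the transform length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralConfig", "SegmentSpectrum", "band_bins", "compute_spectrum"]


def band_bins(f_band_low: float, f_band_high: float, fs: float, n_fft: int) -> tuple[int, int, int]:
    """Map analysis-band edges to FFT bin indices.

    Edges are rounded to the nearest bin (half away from zero); the in-band
    count is ``b_high - b_low + 1``.  This is the only edge mapping that
    reproduces the published in-band counts (adult 0.85-3.98 Hz -> 129 bins,
    neonate 1.51-3.66 Hz -> 89 bins at fs=25, N_FFT=1024).
    """
    if not (0 < f_band_low <= f_band_high < fs / 2):
        raise ValueError("need 0 < f_low <= f_high < fs/2")
    b_low = int(np.floor(f_band_low * n_fft / fs + 0.5))
    b_high = int(np.floor(f_band_high * n_fft / fs + 0.5))
    n_band = b_high - b_low + 1
    if n_band < 1:
        raise ValueError("band collapses to zero bins")
    return b_low, b_high, n_band


@dataclass(frozen=True)
class SpectralConfig:
    """Transform length and analysis band for one subject group."""

    f_band_low: float
    f_band_high: float
    n_fft: int = 1024

    def __post_init__(self) -> None:
        if self.n_fft < 2 or self.n_fft & (self.n_fft - 1):
            raise ValueError("N_FFT must be a power of two")

    def resolve(self, fs: float) -> tuple[int, int, int]:
        """(b_low, b_high, N_band) for this band at rate ``fs``."""
        return band_bins(self.f_band_low, self.f_band_high, fs, self.n_fft)


@dataclass
class SegmentSpectrum:
    """Single-sided spectrum of one windowed segment (or a lattice thereof).

    ``X`` and ``P`` carry the frequency axis on axis 0 and any lattice axes
    after it.  ``enbw_bins`` is the window's equivalent noise bandwidth on
    the zero-padded bin grid.
    """

    X: np.ndarray
    P: np.ndarray
    freqs: np.ndarray
    fs: float
    n_fft: int
    band: tuple[int, int]  # (b_low, b_high), inclusive
    enbw_bins: float
    t0: float = 0.0

    @property
    def n_band(self) -> int:
        return self.band[1] - self.band[0] + 1

    def band_slice(self) -> slice:
        return slice(self.band[0], self.band[1] + 1)


def compute_spectrum(
    windowed: np.ndarray,
    window: np.ndarray,
    cfg: SpectralConfig,
    fs: float,
    t0: float = 0.0,
) -> SegmentSpectrum:
    """FFT of a windowed, mean-removed segment, zero-padded to ``N_FFT``.

    ``windowed`` must already carry the taper (the power-spectrum scaling is
    undefined otherwise); the taper itself is passed in for the scaling
    sums.  Time runs along axis 0; trailing axes are lattice dims.
    """
    windowed = np.asarray(windowed, dtype=float)
    window = np.asarray(window, dtype=float)
    n = windowed.shape[0]
    if window.shape != (n,):
        raise ValueError("window length must match segment length")
    if n > cfg.n_fft:
        raise ValueError("segment longer than transform length")
    wsum = window.sum()
    wsqsum = (window**2).sum()
    X = np.fft.rfft(windowed, n=cfg.n_fft, axis=0)
    P = 2.0 * np.abs(X) ** 2 / wsum**2
    freqs = np.fft.rfftfreq(cfg.n_fft, d=1.0 / fs)
    b_low, b_high, _ = cfg.resolve(fs)
    return SegmentSpectrum(
        X=X,
        P=P,
        freqs=freqs,
        fs=fs,
        n_fft=cfg.n_fft,
        band=(b_low, b_high),
        enbw_bins=cfg.n_fft * wsqsum / wsum**2,
        t0=t0,
    )
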