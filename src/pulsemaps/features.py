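"""The 20-map feature bank: per-pixel spatio-temporal and -spectral features.

For each segment and lattice pixel, 19 dynamic features plus a mean-intensity
visual reference are computed and mapped to the pixel's lattice position.
The spectral descriptors follow the standard audio/speech definitions with
the in-band power spectrum treated as a (normalized) distribution
``p_k = P_k / sum(P)`` over bin frequencies ``f_k``:

* band power / band mean power: in-band signal power (ENBW-corrected sum of
  the scaled periodogram) and its per-bin mean;
* band max over band power, spectral crest: peakiness ratios (scale free);
* centroid / spread / skewness / kurtosis: moments of p_k;
* flatness, entropy: geometric-to-arithmetic mean ratio and normalized
  Shannon entropy — near 1 for noise, near 0 for a tonal (pulsatile) signal;
* slope: least-squares slope of P_k on f_k;
* max frequency, phasor amp/phase: location, magnitude and argument of the
  in-band spectral peak;
* spectral fluxes: half-wave-rectified bin-wise power change between two
  subsequent segments, plus their normalized ratios;
* temporal variance: the only dynamic time-domain feature.

Degenerate inputs (an all-zero band, zero spread, zero total flux) take
documented "noise-like"/neutral conventions so every map is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import SegmentSpectrum

__all__ = [
    "FEATURE_IDS",
    "FeatureMap",
    "mean_intensity",
    "temporal_var",
    "band_powers",
    "spectral_moments",
    "spectral_shape",
    "max_frequency_and_phasor",
    "spectral_fluxes",
    "compute_feature_lattice",
    "build_maps",
]

#: bank enumeration; fixed report/export order
FEATURE_IDS = (
    "mean_intensity",
    "band_power",
    "band_mean_power",
    "band_max_over_band_power",
    "spectral_centroid",
    "spectral_spread",
    "spectral_skewness",
    "spectral_kurtosis",
    "spectral_crest",
    "spectral_flatness",
    "spectral_entropy",
    "spectral_slope",
    "max_frequency",
    "phasor_phase",
    "phasor_amp",
    "temporal_var",
    "spectral_flux_pos",
    "spectral_flux_neg",
    "ratio_flux_pos",
    "ratio_flux_neg",
)


@dataclass
class FeatureMap:
    """One feature over the ROI lattice for one segment."""

    values: np.ndarray
    feature_id: str
    t0: float = 0.0
    db_scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.feature_id not in FEATURE_IDS:
            raise ValueError(f"unknown feature id {self.feature_id!r}")


def mean_intensity(raw_series: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the raw (unfiltered) series; the visual reference."""
    return np.asarray(raw_series, dtype=float).mean(axis=0)


def temporal_var(filtered_seg: np.ndarray) -> np.ndarray:
    """Unbiased sample variance of the filtered, pre-window segment."""
    return np.asarray(filtered_seg, dtype=float).var(axis=0, ddof=1)


def _band_arrays(sp: SegmentSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sl = sp.band_slice()
    P = sp.P[sl]
    f = sp.freqs[sl]
    X = sp.X[sl]
    return P, f, X


def band_powers(sp: SegmentSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(band_power, band_mean_power, band_max_over_band_power).

    Band power is the ENBW-corrected in-band periodogram sum, i.e. true
    in-band signal power (0.5 for a unit-amplitude in-band sinusoid),
    independent of zero-padding.  The max/power ratio is scale free; an
    all-zero band takes the flat convention 1/N.
    """
    P, _, _ = _band_arrays(sp)
    n = P.shape[0]
    total = P.sum(axis=0)
    power = total / sp.enbw_bins
    with np.errstate(invalid="ignore", divide="ignore"):
        max_over = np.where(total > 0, P.max(axis=0) / total, 1.0 / n)
    return power, power / n, np.asarray(max_over)


def _p_dist(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized in-band distribution and the all-zero mask."""
    total = P.sum(axis=0)
    zero = total <= 0
    safe = np.where(zero, 1.0, total)
    return P / safe, zero


def spectral_moments(sp: SegmentSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(centroid [Hz], spread [Hz], skewness, kurtosis) of p_k over f_k.

    All-zero band: centroid = band midpoint, spread/skewness/kurtosis = 0.
    Zero spread: skewness and kurtosis 0 by convention.
    """
    P, f, _ = _band_arrays(sp)
    p, zero = _p_dist(P)
    fshape = (-1,) + (1,) * (P.ndim - 1)
    fb = f.reshape(fshape)
    centroid = (fb * p).sum(axis=0)
    mid = 0.5 * (f[0] + f[-1])
    centroid = np.where(zero, mid, centroid)
    d = fb - centroid
    var = (d**2 * p).sum(axis=0)
    spread = np.sqrt(np.where(zero, 0.0, var))
    flat = (spread <= 0) | zero
    s3 = np.where(flat, 1.0, spread**3)
    s4 = np.where(flat, 1.0, spread**4)
    skew = np.where(flat, 0.0, (d**3 * p).sum(axis=0) / s3)
    kurt = np.where(flat, 0.0, (d**4 * p).sum(axis=0) / s4)
    return np.asarray(centroid), np.asarray(spread), np.asarray(skew), np.asarray(kurt)


def spectral_shape(sp: SegmentSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(crest, flatness, entropy, slope).

    crest = max/mean of P_k (in [1, N]); flatness = geometric/arithmetic mean
    (0 if any bin is zero, by the geometric mean); entropy = Shannon entropy
    of p_k normalized by log2 N (in [0, 1]); slope = least-squares slope of
    P_k on f_k [power/Hz].  All-zero band is maximally noise-like:
    crest 1, flatness 1, entropy 1, slope 0.
    """
    P, f, _ = _band_arrays(sp)
    n = P.shape[0]
    total = P.sum(axis=0)
    zero = total <= 0
    mean = total / n
    safe_mean = np.where(zero, 1.0, mean)
    crest = np.where(zero, 1.0, P.max(axis=0) / safe_mean)
    any_zero_bin = (P <= 0).any(axis=0)
    with np.errstate(divide="ignore"):
        logP = np.log(np.where(P > 0, P, 1.0))
    gmean = np.exp(logP.mean(axis=0))
    flatness = np.where(zero, 1.0, np.where(any_zero_bin, 0.0, gmean / safe_mean))
    p, _ = _p_dist(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = np.where(zero, 1.0, -plogp.sum(axis=0) / np.log2(n))
    fshape = (-1,) + (1,) * (P.ndim - 1)
    fb = f.reshape(fshape)
    fm = f.mean()
    denom = ((f - fm) ** 2).sum()
    slope = (((fb - fm) * (P - mean)).sum(axis=0)) / denom
    return np.asarray(crest), np.asarray(flatness), np.asarray(entropy), np.asarray(slope)


def max_frequency_and_phasor(sp: SegmentSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(max_frequency [Hz], phasor_amp, phasor_phase [rad]) at the in-band peak.

    Argmax ties break toward the lowest bin; an all-zero band reports the
    lower band edge with amplitude 0 and phase 0.
    """
    P, f, X = _band_arrays(sp)
    kstar = P.argmax(axis=0)
    fmax = f[kstar]
    Xstar = np.take_along_axis(X, kstar[None], axis=0)[0]
    amp = np.abs(Xstar)
    phase = np.where(amp > 0, np.angle(Xstar), 0.0)
    return np.asarray(fmax), np.asarray(amp), np.asarray(phase)


def spectral_fluxes(
    sp_prev: SegmentSpectrum, sp_curr: SegmentSpectrum
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(flux_pos, flux_neg, ratio_flux_pos, ratio_flux_neg) between two segments.

    Half-wave-rectified bin-wise in-band power change; when nothing changed
    both ratios take the neutral value 0.5.
    """
    P0, _, _ = _band_arrays(sp_prev)
    P1, _, _ = _band_arrays(sp_curr)
    if P0.shape != P1.shape:
        raise ValueError("spectra must share the band and lattice")
    d = P1 - P0
    pos = np.clip(d, 0, None).sum(axis=0)
    neg = np.clip(-d, 0, None).sum(axis=0)
    total = pos + neg
    safe = np.where(total > 0, total, 1.0)
    r_pos = np.where(total > 0, pos / safe, 0.5)
    r_neg = np.where(total > 0, neg / safe, 0.5)
    return pos, neg, np.asarray(r_pos), np.asarray(r_neg)


def compute_feature_lattice(
    raw_seg: np.ndarray,
    filtered_seg: np.ndarray,
    sp: SegmentSpectrum,
    sp_prev: SegmentSpectrum | None = None,
) -> dict[str, np.ndarray]:
    """All 20 features for one segment over the full lattice.

    ``raw_seg``/``filtered_seg`` have time on axis 0 and lattice dims after.
    When no predecessor spectrum exists (first segment of a run) the fluxes
    take the no-change convention.
    """
    power, mean_power, max_over = band_powers(sp)
    centroid, spread, skew, kurt = spectral_moments(sp)
    crest, flatness, entropy, slope = spectral_shape(sp)
    fmax, amp, phase = max_frequency_and_phasor(sp)
    pos, neg, r_pos, r_neg = spectral_fluxes(sp_prev if sp_prev is not None else sp, sp)
    return {
        "mean_intensity": mean_intensity(raw_seg),
        "band_power": power,
        "band_mean_power": mean_power,
        "band_max_over_band_power": max_over,
        "spectral_centroid": centroid,
        "spectral_spread": spread,
        "spectral_skewness": skew,
        "spectral_kurtosis": kurt,
        "spectral_crest": crest,
        "spectral_flatness": flatness,
        "spectral_entropy": entropy,
        "spectral_slope": slope,
        "max_frequency": fmax,
        "phasor_phase": phase,
        "phasor_amp": amp,
        "temporal_var": temporal_var(filtered_seg),
        "spectral_flux_pos": pos,
        "spectral_flux_neg": neg,
        "ratio_flux_pos": r_pos,
        "ratio_flux_neg": r_neg,
    }


def build_maps(lattice_features: dict[str, np.ndarray], t0: float = 0.0) -> dict[str, FeatureMap]:
    """Assemble the per-pixel features of one segment into the 20-map bank."""
    missing = set(FEATURE_IDS) - set(lattice_features)
    if missing:
        raise ValueError(f"missing features: {sorted(missing)}")
    shapes = {np.asarray(v).shape for v in lattice_features.values()}
    if len(shapes) != 1:
        raise ValueError("all feature lattices must share the ROI-lattice dims")
    return {
        fid: FeatureMap(values=np.asarray(lattice_features[fid]), feature_id=fid, t0=t0)
        for fid in FEATURE_IDS
    }
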