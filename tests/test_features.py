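"""The 20-feature bank: closed-form examples, conventions, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsemaps import FEATURE_IDS, SpectralConfig, apply_window, compute_spectrum
from pulsemaps.features import (
    FeatureMap,
    band_powers,
    build_maps,
    compute_feature_lattice,
    max_frequency_and_phasor,
    mean_intensity,
    spectral_fluxes,
    spectral_moments,
    spectral_shape,
    temporal_var,
)
from pulsemaps.spectral import SegmentSpectrum

FS = 25.0


def make_spectrum(P_band, f0=1.0, df=0.1, X_band=None, enbw=1.0):
    """Embed an in-band power vector into a synthetic SegmentSpectrum.

    With enbw=1 the band-power feature reduces to the plain in-band sum,
    which keeps the closed-form examples below exact.
    """
    P_band = np.asarray(P_band, dtype=float)
    n = P_band.shape[0]
    b_low = 10
    total_bins = b_low + n + 10
    P = np.zeros((total_bins,) + P_band.shape[1:])
    P[b_low : b_low + n] = P_band
    if X_band is None:
        X_band = np.sqrt(P_band).astype(complex)
    X = np.zeros((total_bins,) + P_band.shape[1:], dtype=complex)
    X[b_low : b_low + n] = X_band
    freqs = f0 + (np.arange(total_bins) - b_low) * df
    return SegmentSpectrum(
        X=X, P=P, freqs=freqs, fs=FS, n_fft=2 * (total_bins - 1),
        band=(b_low, b_low + n - 1), enbw_bins=enbw,
    )


class TestTemporalFeatures:
    @pytest.mark.parametrize(
        "series,expected",
        [
            (np.full(250, 3.0), 3.0),
            (np.tile([0.0, 2.0], 125), 1.0),
            (np.arange(250.0), 124.5),
        ],
    )
    def test_mean_intensity(self, series, expected):
        assert mean_intensity(series) == pytest.approx(expected)

    def test_temporal_var_zero_segment(self):
        assert temporal_var(np.zeros(250)) == 0.0

    def test_temporal_var_alternating_unbiased(self):
        x = np.tile([-1.0, 1.0], 125)
        assert temporal_var(x) == pytest.approx(250 / 249)

    def test_temporal_var_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(250)
        assert temporal_var(3.0 * x) == pytest.approx(9.0 * temporal_var(x))


class TestBandPowers:
    def test_single_nonzero_bin(self):
        P = np.zeros(8)
        P[3] = 4.2
        power, mean_p, max_over = band_powers(make_spectrum(P))
        assert power == pytest.approx(4.2)
        assert mean_p == pytest.approx(4.2 / 8)
        assert max_over == pytest.approx(1.0)

    def test_flat_band(self):
        power, mean_p, max_over = band_powers(make_spectrum(np.full(10, 0.3)))
        assert power == pytest.approx(3.0)
        assert mean_p == pytest.approx(0.3)
        assert max_over == pytest.approx(0.1)

    def test_all_zero_band_conventions(self):
        power, mean_p, max_over = band_powers(make_spectrum(np.zeros(5)))
        assert power == 0.0 and mean_p == 0.0
        assert max_over == pytest.approx(1 / 5)

    def test_unit_sinusoid_calibration(self):
        """End-to-end scaling oracle: window + zero-padded FFT + ENBW sum = A^2/2."""
        cfg = SpectralConfig(f_band_low=0.85, f_band_high=3.98, n_fft=1024)
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * (82 * FS / 1024) * t)
        win, w = apply_window(x - x.mean())
        power, _, _ = band_powers(compute_spectrum(win, w, cfg, FS))
        assert power == pytest.approx(0.5, rel=0.02)


class TestSpectralMoments:
    def test_single_bin_mass(self):
        P = np.zeros(9)
        P[4] = 2.0
        c, s, sk, k = spectral_moments(make_spectrum(P, f0=1.0, df=0.1))
        assert c == pytest.approx(1.4)
        assert s == 0.0 and sk == 0.0 and k == 0.0

    def test_flat_band_symmetric(self):
        c, s, sk, k = spectral_moments(make_spectrum(np.full(11, 1.0), f0=2.0, df=0.2))
        assert c == pytest.approx(3.0)  # band midpoint
        assert abs(sk) < 1e-12

    def test_two_point_distribution(self):
        P = np.zeros(11)
        P[0] = P[10] = 1.0
        c, s, sk, k = spectral_moments(make_spectrum(P, f0=1.0, df=0.1))
        assert c == pytest.approx(1.5)
        assert s == pytest.approx(0.5)  # |f2 - f1| / 2
        assert sk == pytest.approx(0.0, abs=1e-12)
        assert k == pytest.approx(1.0)

    def test_all_zero_band_midpoint(self):
        c, s, sk, k = spectral_moments(make_spectrum(np.zeros(11), f0=1.0, df=0.1))
        assert c == pytest.approx(1.5)
        assert s == 0.0 and sk == 0.0 and k == 0.0


class TestSpectralShape:
    def test_flat_band(self):
        crest, flat, ent, slope = spectral_shape(make_spectrum(np.full(16, 0.7)))
        assert crest == pytest.approx(1.0)
        assert flat == pytest.approx(1.0)
        assert ent == pytest.approx(1.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_single_nonzero_bin(self):
        P = np.zeros(16)
        P[5] = 1.0
        crest, flat, ent, _ = spectral_shape(make_spectrum(P))
        assert crest == pytest.approx(16.0)
        assert flat == 0.0
        assert ent == pytest.approx(0.0, abs=1e-12)

    def test_linear_power_slope_recovered(self):
        f0, df = 1.0, 0.1
        f = f0 + np.arange(12) * df
        P = 0.8 * f + 2.0
        _, _, _, slope = spectral_shape(make_spectrum(P, f0=f0, df=df))
        assert slope == pytest.approx(0.8)

    def test_all_zero_band_noise_like(self):
        crest, flat, ent, slope = spectral_shape(make_spectrum(np.zeros(8)))
        assert crest == 1.0 and flat == 1.0 and ent == 1.0 and slope == 0.0


class TestMaxFrequencyAndPhasor:
    def test_grid_sinusoid_peak_location_and_phase(self):
        cfg = SpectralConfig(f_band_low=0.85, f_band_high=3.98, n_fft=1024)
        f0 = 82 * FS / 1024  # ~2.002 Hz, on the zero-padded bin grid
        t = np.arange(250) / FS
        x = np.cos(2 * np.pi * f0 * t)  # cosine aligned with segment start
        win, w = apply_window(x - x.mean())
        sp = compute_spectrum(win, w, cfg, FS)
        fmax, amp, phase = max_frequency_and_phasor(sp)
        assert abs(fmax - f0) <= FS / 1024
        assert phase == pytest.approx(0.0, abs=0.05)

    def test_amp_scales_linearly(self):
        P = np.zeros(8)
        P[2] = 1.0
        sp1 = make_spectrum(P, X_band=np.sqrt(P).astype(complex))
        sp3 = make_spectrum(9 * P, X_band=3 * np.sqrt(P).astype(complex))
        _, a1, _ = max_frequency_and_phasor(sp1)
        _, a3, _ = max_frequency_and_phasor(sp3)
        assert a3 == pytest.approx(3 * a1)

    def test_all_zero_band_conventions(self):
        fmax, amp, phase = max_frequency_and_phasor(make_spectrum(np.zeros(8), f0=1.0))
        assert fmax == pytest.approx(1.0)  # lower band edge
        assert amp == 0.0 and phase == 0.0

    def test_argmax_tie_breaks_low(self):
        P = np.zeros(8)
        P[2] = P[5] = 1.0
        fmax, _, _ = max_frequency_and_phasor(make_spectrum(P, f0=1.0, df=0.1))
        assert fmax == pytest.approx(1.2)


class TestSpectralFluxes:
    def test_identical_spectra(self):
        sp = make_spectrum(np.arange(8.0))
        pos, neg, rp, rn = spectral_fluxes(sp, sp)
        assert pos == 0.0 and neg == 0.0
        assert rp == 0.5 and rn == 0.5

    def test_single_bin_increase(self):
        P = np.full(8, 1.0)
        Q = P.copy()
        Q[3] += 0.7
        pos, neg, rp, rn = spectral_fluxes(make_spectrum(P), make_spectrum(Q))
        assert pos == pytest.approx(0.7)
        assert neg == 0.0
        assert rp == pytest.approx(1.0) and rn == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ratio_complementarity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(8), rng.random(8)
        _, _, rp, rn = spectral_fluxes(make_spectrum(a), make_spectrum(b))
        assert rp + rn == pytest.approx(1.0)
        assert 0.0 <= rp <= 1.0


class TestBankInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        n = 16
        sp = make_spectrum(rng.random(n), f0=1.0, df=0.1)
        _, _, max_over = band_powers(sp)
        c, _, _, _ = spectral_moments(sp)
        crest, flat, ent, _ = spectral_shape(sp)
        assert 0.0 <= flat <= 1.0 + 1e-12
        assert 0.0 <= ent <= 1.0 + 1e-12
        assert 1.0 - 1e-12 <= crest <= n
        assert 1.0 <= c <= 1.0 + (n - 1) * 0.1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_couplings_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = 16
        sp = make_spectrum(rng.random(n))
        power, mean_p, max_over = band_powers(sp)
        crest, _, _, _ = spectral_shape(sp)
        assert power == pytest.approx(n * mean_p, rel=1e-12)
        assert crest == pytest.approx(n * max_over, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        P = rng.random(16)
        perm = rng.permutation(16)
        sp, sp_p = make_spectrum(P), make_spectrum(P[perm])
        assert band_powers(sp)[0] == pytest.approx(band_powers(sp_p)[0])
        a, b = spectral_shape(sp), spectral_shape(sp_p)
        assert a[0] == pytest.approx(b[0])  # crest
        assert a[1] == pytest.approx(b[1])  # flatness
        assert a[2] == pytest.approx(b[2])  # entropy
        # order-sensitive features do change
        assert spectral_moments(sp)[0] != pytest.approx(spectral_moments(sp_p)[0])


class TestBuildMaps:
    def _lattice_features(self, shape=(3, 4)):
        rng = np.random.default_rng(0)
        raw = rng.random((250,) + shape)
        filt = raw - raw.mean(axis=0)
        P = rng.random((8,) + shape)
        sp = make_spectrum(P)
        return compute_feature_lattice(raw, filt, sp)

    def test_bank_is_complete_and_shaped(self):
        feats = self._lattice_features()
        bank = build_maps(feats, t0=0.0)
        assert set(bank) == set(FEATURE_IDS)
        assert len(bank) == 20
        assert all(bank[fid].values.shape == (3, 4) for fid in FEATURE_IDS)

    def test_first_segment_flux_convention(self):
        feats = self._lattice_features()
        assert np.all(feats["ratio_flux_pos"] == 0.5)
        assert np.all(feats["spectral_flux_pos"] == 0.0)

    def test_missing_feature_rejected(self):
        feats = self._lattice_features()
        feats.pop("spectral_crest")
        with pytest.raises(ValueError):
            build_maps(feats)

    def test_distinct_pixels_keep_their_positions(self):
        P = np.zeros((8, 2, 2))
        P[1, 0, 0] = 1.0  # pixel (0,0) peaks at bin 1
        P[5, 1, 1] = 1.0  # pixel (1,1) peaks at bin 5
        sp = make_spectrum(P, f0=1.0, df=0.1)
        fmax, _, _ = max_frequency_and_phasor(sp)
        assert fmax[0, 0] == pytest.approx(1.1)
        assert fmax[1, 1] == pytest.approx(1.5)

    def test_unknown_feature_id_rejected(self):
        with pytest.raises(ValueError):
            FeatureMap(values=np.zeros((2, 2)), feature_id="not_a_feature")
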