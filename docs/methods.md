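# Methods

This note documents the models, conventions and numerical choices behind
`pulsemaps`, and what the synthetic-scene tests do and do not demonstrate
about real recordings.

## Processing chain

The chain treats every pooled lattice pixel as an independent
one-dimensional signal and describes it per sliding segment.

**ROI generation.** Frames are convolved with a normalized 2-D Gaussian
(outer product of sampled 1-D Gaussians, renormalized to unit sum so
constant regions are preserved) in *valid* mode — no border padding — and
then decimated. Valid convolution is the only border mode consistent with
the published lattice sizes: (1920 − 41 + 1)/5 = 376 and 480 − 33 + 1 = 448.
The decimation grid is anchored at patch centers (first kept index
`floor((d−1)/2)`), so each lattice pixel sits at the center of its pooling
support.

**Temporal filtering.** Within each `N_seg`-sample window the temporal mean
is removed first, then an order-6 Butterworth bandpass (`scipy` second-order
sections; half-power cutoffs at the configured band edges) is applied
forward–backward. Zero-phase filtering doubles the effective order to 12 and
squares the magnitude response; edge transients are initialized by scipy's
odd-padding scheme. This initialization is not exactly time-reversal
symmetric, so reversal symmetry holds only away from roughly one transient
length (~60 samples) at each end — the Hann taper applied next strongly
attenuates exactly that region. Segments shorter than three filter orders
are rejected as unreliable.

**Spectral analysis.** The windowed segment is zero-padded to
`N_FFT = 1024` and transformed with a real FFT. The single-sided power
spectrum is scaled `P[k] = 2|X[k]|²/(Σw)²` — the amplitude-correct scaling
in which a unit sinusoid's spectral peak reads `A²/2 = 0.5`. The analysis
band is mapped to bins by rounding each edge to the nearest bin
(half-away-from-zero); this is the only rounding rule that yields 129 bins
for 0.85–3.98 Hz and 89 for 1.51–3.66 Hz at 25 Hz / 1024 points (floor or
ceil give 128/88).

### Band power and the equivalent noise bandwidth

Zero-padding oversamples the window's main lobe by `N_FFT/N_win ≈ 4.1`, so a
plain sum of `P[k]` across a band overcounts the power of a coherent signal
(a unit sinusoid would sum to ≈ 3.07, and the total would grow linearly with
`N_FFT`). The band-power and band-mean-power features therefore divide the
in-band sum by the window's equivalent noise bandwidth in bins,

    ENBW = N_FFT · Σw² / (Σw)²   (= 6.144 for a periodic Hann of 250 at 1024),

which restores the physically meaningful quantity: the in-band signal power,
0.5 for a unit-amplitude in-band sinusoid, independent of the transform
length. All *ratio* features (band-max/band-power, crest, flatness, entropy,
flux ratios) are scale-free and unaffected; the exact couplings
`band_power = N_band · band_mean_power` and
`crest = N_band · (max/Σ)` hold by construction.

### Feature conventions

Spectral descriptors follow the standard audio/speech definitions on the
normalized in-band distribution `p_k = P_k/ΣP`. Degenerate inputs take
documented, maximally noise-like conventions so every map is total:

| situation | convention |
|---|---|
| all-zero band | band powers 0; max/Σ = 1/N; centroid = band midpoint; spread, skewness, kurtosis, slope = 0; crest, flatness, entropy = 1; max frequency = lower band edge; phasor amp/phase = 0 |
| zero spread | skewness = kurtosis = 0 |
| any zero bin | flatness = 0 (geometric mean) |
| zero total flux | both flux ratios = 0.5 |
| first segment of a run | fluxes computed against itself (0, ratios 0.5) |

Argmax ties break toward the lowest bin. Entropy uses base-2 logarithms
normalized by `log₂N` (any base is equivalent after normalization). The
spectral slope is regressed on raw (not dB) power. The phasor is taken at
each pixel's own in-band argmax bin, not at a global frequency.

## Postprocessing

The dB policy assigns `U = 10` to power-like maps (band powers, temporal
variance, fluxes), `U = 20` to the amplitude-like phasor magnitude, and
leaves bounded/ratio/frequency/phase maps linear. The stabilizer defaults
to `ε = 1e−12` (configurable); maps are normalized min–max over all pixels
(a constant map normalizes to zeros) and quantized by
`min(floor(x·N_scale), N_scale−1)`. Display rendering uses manual window
limits only — the package never auto-fits the display window.

Similarity maps use the naive per-pixel patch histogram (31×31, symmetric
reflection at boundaries) as the reference semantics; an integral-histogram
acceleration would be possible but is unnecessary at the lattice sizes the
chain produces. RMS contrast is computed on the normalized (pre-quantization)
map with divisor `N−1`; evaluation on the quantized map is available by
quantizing first.

## Synthetic scenes

Real recordings of subjects are not redistributable, so all end-to-end
tests run on generated scenes with the structure the chain assumes:

* static baseline (default 100 intensity units) plus i.i.d. Gaussian sensor
  noise (default SD 1; an AR(1) option models temporally correlated noise);
* a pulsatile subject — filled ellipse (PPGI-like "silhouette" mode) or
  2-pixel ring (IRT-like "contour" mode) — oscillating at the pulse
  frequency (default 1.5 Hz = 90 bpm, amplitude 3, i.e. amplitude-to-noise
  3);
* a smooth multiplicative amplitude texture over the subject (relative SD
  0.3, floored at 0.2). Real subjects never pulse with spatially uniform
  amplitude — perfusion, geometry and shading vary — and without this term
  the pulsatile region would be near-constant in every power map and its
  RMS contrast would *fall below* the background's, inverting the
  qualitative behaviour the chain is designed to expose;
* optional confounders: an "eyes" sub-region at its own frequency, a
  reflection patch carrying a scaled copy of the pulse, global multiplicative
  illumination flicker, and a slowly ramping cast-shadow strip.

Ground truth is delivered on the ROI lattice: *foreground* pixels have
Gaussian-pooled modulation weight ≥ 90 % of the maximum (pooling support
essentially pure subject), *background* pixels ≤ 1 % with no other dynamic
region reaching them. For region evaluation the ground truth also provides
`pulse_region`, the bounding rectangle of the visible modulation extent
(pooled weight ≥ 5 %): this is the kind of big, manually boxed pulsatile ROI
an operator draws over a subject, and it deliberately mixes pulsatile,
boundary and background pixels — the mixture is what gives pulsatile regions
their large flatness/entropy spread in practice.

**What passing tests show — and don't.** The scenes verify the chain's
discriminative mechanics: tonal vs. noise-like spectra separate in
flatness/entropy, in-band power localizes the subject, the max-frequency
map recovers the generator frequency within one FFT bin, and
histogram-intersection maps score background above subject. They do not
model skin optics, thermal radiation physics, waveform morphology
(harmonics, heart-rate variability), subject motion beyond the confounder
terms, or camera nonlinearities — conclusions about real recordings still
require real recordings.

## Problem sizes and defaults

Tests and examples run the chain at a desk scale chosen by the package:
scenes of 140×180 pixels pooled with a 9-pixel kernel (σ = 2) and decimation
2 to a 66×86 lattice, 10 s at 25 Hz. The published full-resolution
parametrizations are available as the presets `paper-adult-ppgi`,
`paper-baby-ppgi` and `paper-irt` and are exercised directly for the
configuration-arithmetic checks (lattice sizes, band bins). The default
segment hop is a full segment (non-overlapping maps); single-sample hop
(249-sample overlap) is supported but costs `N_seg` times more transforms.

## Known limitations

* Lossless video containers are not read; clips exchange as multi-page TIFF
  or raw frames with a plain-text sidecar header.
* Dropped-frame repair needs timestamps or an explicit drop list, and
  cannot extrapolate gaps at the sequence boundary.
* The `paper-irt` preset pairs the IRT ROI stage with the adult band by
  default (a `subject` switch selects the neonate band); the temporal and
  spectral stages are shared between modalities.
* The similarity computation is the naive reference implementation;
  full-resolution similarity maps at hop 1 are expensive.
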