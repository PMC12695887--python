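# Methods

## Signal model

A photoacoustic (PA) trace is modelled as a sum of exponentially damped
sinusoids launched at the acoustic arrival time τ = d/c (particle-to-
resonator distance d over sound speed c, 1480 m/s by default), plus
additive white Gaussian detector noise:

    x(t) = Σ_i A_i · exp(−(t−τ)/T_i) · sin(2π f_i (t−τ) + φ_i) · 1[t ≥ τ] + n(t)

Each class (a red-blood-cell species, a whole-blood sample, or a gold-
nanoparticle geometry) is a `SpeciesTemplate`: a set of components
(f_i, A_i, T_i, φ_i) plus per-measurement multiplicative jitter on
amplitudes and frequencies. The delay is a pure time shift — no
attenuation or dispersion is modelled, since only the existence of the
distance-dependent delay is established for the instrument.

Defaults that matter:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 100 MHz | Nyquist (50 MHz) far above the ~4 MHz PA band |
| record length | 50 µs | covers a multi-µs ring-down; 5000 samples keeps tests fast |
| amplitude jitter | 5 % (rel. std) | measurement-to-measurement intensity variation |
| frequency jitter | 0.1 % (rel. std) | vibration frequencies are conserved across repeated measurements of the same sample; the 3.9 MHz sheep peak must stay within one 20 kHz FFT bin |
| whole-blood variability scale | 3× | the complex matrix produces visibly larger deviations between measurements; the exact factor is unquantified, 3× makes the raw-feature PCA visibly noisier without destroying class structure |
| target SNR | 35 dB | the instrument reports > 30 dB; 35 leaves margin for estimator variance |
| concentration slope | 2.5 mV mL fM⁻¹ | linear-region response of PA amplitude vs nanoparticle concentration (the printed unit is carried verbatim; numerically fM in, mV out) |

Species templates are invented emulations constrained by the printed
facts: every red-blood-cell species keeps its dominant component within
3.5–4.5 MHz (sheep pinned at 3.9 MHz), species identity lives in ≤ 0.3 MHz
dominant-frequency offsets plus distinct low-amplitude secondary
components, so the spectra "look alike" while remaining machine-
separable. Whole blood swaps llama for horse and spreads the secondary
components further apart so the fingerprints survive the tripled jitter.
The four nanoparticle geometries differ strongly in both dominant
frequency and damping; their pairwise noiseless-spectrum cosine
similarities are all below 0.2.

### Seeding

A single integer seed governs everything. Datasets derive per-signal
seeds via `SeedSequence(seed, spawn_key=(class_idx, sample_idx))`, so any
individual trace is reproducible independently of generation order, and
identical (template, config, seed) triples give bitwise-identical arrays.

### SNR calibration

SNR is defined as the one-sided band power in the dominant-peak band
(peak ± 0.5 MHz) over the total broadband noise power, where the noise
power is read off the 20–40 MHz band and extrapolated over 0–Nyquist
(white-noise assumption). For a tone over white noise this reduces to the
familiar 20·log10(RMS_tone/RMS_noise). The band locations are package
choices — the instrument's own SNR procedure is not documented — and the
far noise band avoids leakage from the PA band. One subtlety: the gated
transient itself leaks a small amount of power into the noise band
(spectral tails), which a band-power estimator cannot distinguish from
noise. When a target SNR is requested, the generator therefore solves for
the noise level that makes the *estimator's* reading equal the target,
subtracting the render's known leakage. Calibration is accurate to well
under 1 dB at the default settings; a noiseless narrowband record (empty
noise band) reports a +200 dB cap rather than infinity.

## Spectral analysis

Spectra are one-sided FFT magnitudes with no window — the records are
gated transients that decay to the noise floor before the record ends, so
a window would only smear the peaks. Parseval's identity under this
convention (`sum(x²) = (1/N)·Σ w_k·|X_k|²`, w = 2 except DC/Nyquist) is
property-tested to 1e−9 relative. Dominant-peak search defaults to the
1–10 MHz band; ties break toward the lower frequency.

Delay estimation finds the first run of 3 consecutive samples exceeding
5× a robust noise scale (1.4826·MAD of the final 10 % of the record,
where the ring-down has decayed). A missing onset raises a distinct
not-detected error rather than returning 0.

The concentration fitter takes the *longest prefix* of the (strictly
increasing) concentration series whose ordinary-least-squares r² is
≥ 0.99 — "linear region" is not otherwise defined — and reports the OLS
slope/intercept on it. A perfectly flat series counts as linear with
slope 0 (zero-residual convention).

Library matching resamples the query onto the library grid (linear
interpolation), normalises to unit energy, and ranks by cosine
similarity; ties keep library order.

## Feature extractor and prototype learning

The extractor is a small 1-D CNN over spectrum bins: two valid-mode
convolution stages (widths 9 and 5, 16 and 32 channels) each followed by
ReLU and width-4 max-pooling, then flatten and a fully connected layer
with ReLU to D = 32 features. Architecture details (widths, channels,
pool type, D) are package defaults — the study specifies only the
conv → pool → flatten → FC(ReLU) shape — chosen to train in seconds on one
CPU; all are configurable. Inputs are magnitude spectra resampled to 512
uniform bins over 0–12.5 MHz and scaled to unit maximum, so
classification keys on spectral shape rather than amplitude (which varies
with concentration). The network and its backpropagation are implemented
directly on numpy, which keeps training bit-deterministic for a given
seed.

Prototype learning places one trainable embedding m_y per class (K = 1;
general K is supported with per-class distance = min over the K
prototypes). Prediction is nearest-prototype by Euclidean distance;
probabilities are the softmax of negative distances, computed with a
max-shift (the result is invariant under a common shift of all
distances); CE = −log p(y|x) with natural log and a 1e−12 clamp;
PL = squared distance to the true-class prototype; total loss
CE + λ·PL with λ = 0.1. Extractor parameters and prototypes are updated
jointly by Adam (lr 1e−3, batch 16, 100 epochs by default) on the 80 %
stratified training split. Prototypes initialise from seeded N(0, 0.1)
draws; an optional flag warm-starts them at the class means of the
initial features. Training aborts with a diagnostic if the loss becomes
non-finite.

A note on the λ trade-off: early in training the cross-entropy term
expands the feature scale (larger margins between classes), so the mean
feature-to-prototype distance can transiently rise; as p(y|x) saturates
the CE gradient vanishes and the prototype pull dominates, contracting
each class onto its prototype. Across λ ∈ {0, 0.1, 1} the final
feature-to-prototype distance is non-increasing in λ.

Separate sample types (washed cells vs whole blood) are trained as
separate models of the same architecture; trained artifacts are
immutable, so training one can never mutate another.

## Evaluation

PCA projections are mean-centred with a fixed sign convention (the
largest-magnitude loading of each axis is positive) and, like the paper's
visualisation, are fit on the test samples only. "Raw" features are the
unit-max-normalised spectrum vectors on the network input grid. Cluster
separation is summarised by the mean silhouette coefficient of the 2-D
projection; the package's quantitative restatement of the qualitative
raw-vs-learned contrast is the invariant silhouette_learned >
silhouette_raw on both the cell and whole-blood generators. Evaluation
reports include the confusion matrix, accuracy (= trace/total by
construction), and per-class recall. Test sets too small for a silhouette
(a singleton class, or < 3 points) report NaN silhouettes instead of
failing.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis relies
on — conserved dominant frequencies with species-specific offsets and
secondary components, calibrated SNR, larger whole-blood variability,
linear concentration response, distance-dependent delay — but not the
physics behind it: no thermoelastic wave generation, no optical
absorption cross-sections, no resonator transduction, no frequency-
dependent acoustic attenuation. Passing tests therefore demonstrate that
the pipeline recovers what the generator encodes (peaks, SNR, slopes,
delays, class structure), not that real instrument data would be
classified at the same accuracy; with the default templates the synthetic
classes are cleanly separable and the 5-class test accuracy saturates at
1.0.

## Problem sizes

Default datasets are 40 traces per class (200 signals for 5 classes) of
5000 samples each; training runs 100 epochs in ~10 s on one CPU. Property
tests that sweep training configurations (e.g. the λ sweep over 5 seeds)
use reduced settings — 2 classes, 128-bin inputs, ~25 epochs — which are
sufficient to exhibit the properties being checked.

## Known limitations

- The CE term uses natural log; only the CE scale depends on this choice.
- Band-power SNR is leakage-limited: for noiseless wideband transients it
  reports the (finite) signal-to-leakage ratio, not the cap.
- The linear-region rule (longest r² ≥ 0.99 prefix) can shorten the
  region under heavy noise; the fitter requires at least 3 linear points.
- No open-set rejection: every query is assigned to some class; the
  maximum class probability is the only confidence measure.
- Real waveform ingestion expects uniform two-column delimited text plus
  a JSON manifest; no instrument binary formats are parsed.
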