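# pafingerprint

Photoacoustic (PA) fingerprinting analysis for optofluidic microresonator
sensing: classify nanoparticles and blood cells from the MHz-band acoustic
signatures they emit under pulsed-laser excitation.

In a whispering-gallery-mode microbubble sensor, a particle or cell flowing
through the capillary absorbs a ~20 ns laser pulse, undergoes thermoelastic
expansion, and launches an acoustic transient that the optical resonance
reads out. The time trace is a sum of damped sinusoids whose frequency
content — the *PA fingerprint* — reflects the emitter's shape, composition
and morphology. This package implements the full analysis chain for such
measurements, with a synthetic generator standing in for the (non-public)
instrument data:

- **`synth`** — seeded generation of labeled PA traces: red-blood-cell
  spectra sharing a dominant peak near 4 MHz (sheep at 3.9 MHz), whole-blood
  variants with larger measurement-to-measurement variability, and four
  spectrally distinct gold-nanoparticle geometries (sphere, rod, cube,
  shell); amplitude linear in concentration at 2.5 mV mL fM⁻¹; acoustic
  delay τ = distance / sound speed.
- **`signal`** — one-sided FFT spectra, dominant-peak search, band-power
  SNR, onset-based delay estimation, linear-region concentration fits, and
  cosine spectral-library matching.
- **`features`** — a 1-D CNN feature extractor f(x, q) over spectrum bins
  (conv → ReLU → max-pool stages, flatten, fully connected + ReLU), written
  directly on numpy with hand-rolled backpropagation.
- **`prototype`** — prototype learning: each class y owns an embedding
  m_y in the latent space; prediction is nearest-prototype by Euclidean
  distance, class probabilities are p(y|x) = e^{−‖f(x,q)−m_y‖} / Σ_k
  e^{−‖f(x,q)−m_k‖}, and training jointly minimises
  loss = CE + λ·PL with CE = −log p(y|x), PL = ‖f(x,q)−m_y‖², λ = 0.1,
  on an 80/20 stratified split. Exposed as the scikit-learn-compatible
  estimator `PrototypeNetClassifier`.
- **`evaluate`** — confusion matrices, PCA projections of raw vs learned
  features, and silhouette scores quantifying how much better the learned
  embedding separates the classes.
- **`cli`** — the `pafp` command (`simulate`, `spectrum`, `snr`, `delay`,
  `concfit`, `match`, `train`, `classify`, `evaluate`).

## Worked example

```python
import pafingerprint as pf
from pafingerprint.prototype import TrainConfig, split_dataset, train
from pafingerprint.evaluate import evaluate

# 5 species of washed red blood cells, 40 traces each, 100 MHz / 50 us
templates = pf.default_templates("rbc_species")
dataset = pf.generate_dataset(templates, 40, pf.AcquisitionConfig(seed=1))

sig = dataset.signals[40]                      # a sheep trace
spec = pf.compute_spectrum(sig)
f0, _ = pf.dominant_peak(spec)
print(f"{sig.label}: dominant peak {f0/1e6:.2f} MHz, "
      f"SNR {pf.estimate_snr(sig).snr_db:.1f} dB")

clf = train(dataset, train_config=TrainConfig(seed=1))   # CE + 0.1*PL
_, test_set, _ = split_dataset(dataset, 0.8, True, 1)
rep = evaluate(clf, test_set)
print(f"test accuracy {rep.accuracy:.2f}, silhouette raw {rep.silhouette_raw:.2f}"
      f" -> learned {rep.silhouette_learned:.2f}")
```

prints

```
sheep: dominant peak 3.90 MHz, SNR 35.0 dB
test accuracy 1.00, silhouette raw 0.95 -> learned 0.99
```

The sheep fingerprint keeps its 3.9 MHz peak, generation is calibrated to a
35 dB band-power SNR, and training lifts the PCA silhouette of the
held-out samples from 0.95 (raw spectra) to 0.99 (learned features) —
i.e. the prototype-learning CNN tightens each species into its own cluster.

The same flow from a shell:

```bash
pafp simulate --kind rbc_species --n-per-class 40 --seed 1 --out data/rbc
pafp train data/rbc/manifest.json --out runs/rbc --seed 1
pafp classify runs/rbc/classifier.npz data/rbc/signal_00042_sheep.tsv
```

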