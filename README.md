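# mesn — modular echo state networks for EEG band-power classification

Echo state networks (ESNs) classify time series with a fixed random
recurrent layer (the *reservoir*) and a trained linear readout, which
makes them attractive for EEG decoding on small compute budgets — but
their performance hinges on how the reservoir is wired. Biological
cortical networks are not uniformly random: they are *modular*, with
dense within-community wiring and sparse between-community links.
`mesn` builds reservoirs with exactly that structure and provides the
full evaluation protocol around them, for researchers studying
reservoir topology and for EEG-decoding practitioners who want a
lightweight, fully reproducible baseline.

## The model

A reservoir of `N` leaky-integrator tanh units evolves as

```
x(t+1) = (1 − α) x(t) + α · tanh(W_in u(t) + W_rc x(t))
```

and only the readout is trained, by ridge regression:

```
W_out = Y Xᵀ (X Xᵀ + λ I)⁻¹,   y(t) = W_out x(t)
```

The novelty is in `W_rc`: neurons are split into `M` balanced modules;
same-module pairs connect with probability `P1`, cross-module pairs
with probability `P2 ≤ P1`; connections are bidirectional with signed,
truncated-normal weights, and the matrix is rescaled so its spectral
radius equals `ρ = 0.85` (echo-state guard). `M = 1` or `P1 = P2`
recovers the classic random-reservoir "basic ESN".

Around this core the package provides:

* **features** — relative band power (theta/alpha/beta/gamma) of
  non-overlapping, per-channel L2-normalized EEG windows: 4 bands ×
  32 channels = 128 features per window;
* **experiment** — rating binarization (valence/arousal high iff > 5;
  stress/calm rules), repeated 5-fold cross-validation, the exhaustive
  240-triple `(P1, M, P2)` grid search, confusion-matrix metrics;
* **memory_capacity** — delay-reconstruction memory capacity with
  held-out correlation, plus grid sweeps;
* **heterogeneity** — in-degree distributions and their coefficient of
  variation;
* **synthetic** — DEAP-shaped synthetic sessions with controllable
  class-dependent band power, so everything is testable without any
  external download.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import numpy as np
from mesn import (ESNConfig, SyntheticSpec, TopologyConfig, binarize_labels,
                  crop_trials, evaluate_config, extract_features_batch,
                  generate_reservoir, generate_trials, spectral_radius)

# synthetic session: 40 trials, 60 s x 128 Hz x 32 channels
spec = SyntheticSpec(n_trials=40, seed=0)
trials, ratings, _ = generate_trials(spec)
segments, origin = crop_trials(trials, 6.0)          # 6-s windows
features = extract_features_batch(segments, spec.fs)
labels = binarize_labels(ratings, "valence").labels[origin]
print(f"{features.shape[0]} windows x {features.shape[1]} features")

mats = generate_reservoir(
    TopologyConfig(n=600, modules=6, p_intra=0.05, p_inter=0.02, seed=0),
    0.85, n_inputs=128)
print(f"spectral radius: {spectral_radius(mats.w_rc):.10f}")

esn = ESNConfig(alpha=0.25)
modular = TopologyConfig(n=600, modules=6, p_intra=0.05, p_inter=0.02)
basic = TopologyConfig(n=600, modules=1, p_intra=0.05, p_inter=0.05)
for name, topo in [("modular (M=6)", modular), ("basic  (M=1)", basic)]:
    acc = evaluate_config(features, labels, topo, esn, repeats=3, seed=0).mean_accuracy
    print(f"{name} mean 5-fold accuracy: {acc:.4f}")
```

prints

```
400 windows x 128 features
spectral radius: 0.8500000000
modular (M=6) mean 5-fold accuracy: 0.8608
basic  (M=1) mean 5-fold accuracy: 0.8600
```

The 400 windows each carry 128 relative band powers (every channel's
four fractions sum to 1); the generated reservoir hits the 0.85
spectral-radius target to 10 digits; and the modular topology edges out
the matched random baseline on the moderate-effect synthetic valence
task — both accuracies sit well above the 0.5 chance level, and the
margin between topologies is small at this problem size.

The same pipeline is available from the shell:

```sh
mesn synth --trials 40 --seed 0 --out trials.npz
mesn features --input trials.npz --window 6 --out feats.csv
mesn evaluate --config experiment.yaml --out report/
```

Every command writes a `*.manifest.json` recording the configuration,
all seeds and SHA-256 digests of inputs and outputs.

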