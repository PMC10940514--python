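# Methods

## Model

`mesn` implements an echo state network (ESN) whose fixed recurrent
layer ("reservoir") is initialized to a community-structured random
graph instead of the usual Erdős–Rényi one. The reservoir state
`x(t)` of `N` leaky-integrator tanh units evolves as

    x(t+1) = (1 − α) x(t) + α · tanh(W_in u(t) + W_rc x(t))

with leak rate `α ∈ [0, 1]`. Only the linear readout is trained, by
ridge regression in its closed form

    W_out = Y Xᵀ (X Xᵀ + λ I)⁻¹

where the columns of `X` are collected states and of `Y` the one-hot
targets; class decisions are the argmax of `W_out x`, ties toward the
lower class index.

### Modular topology

The reservoir graph is controlled by three parameters:

* `M` — number of modules. The `N` neurons are split into balanced
  modules (sizes differ by at most one) and the assignment is randomly
  permuted. `M = 1` recovers the unpartitioned "basic ESN".
* `P1` — probability that an unordered pair of same-module neurons is
  connected.
* `P2 ≤ P1` — probability for cross-module pairs. `P1 = P2` again
  degenerates to an Erdős–Rényi graph.

Connections are bidirectional: a sampled pair `{i, j}` contributes both
`W[i, j]` and `W[j, i]`, with independent magnitudes drawn from a
standard normal truncated to (0, 1) (a uniform(0, 1) option exists).
Approximately half of all pairs carry opposite signs in their two
directions. Two sign conventions are provided because the prose
formulation "weights in (0, 1) with ~50% of pairs in opposite sign" is
ambiguous:

* `symmetric` (default) — each pair draws one shared random sign and,
  with probability 1/2, one randomly chosen direction is negated.
  Every entry is marginally sign-balanced, so the expected weight
  matrix is zero.
* `flip_one` — base weights stay positive; only the flipped direction
  of an opposite pair is negative. The positive mean weight gives the
  expected adjacency a block structure whose `M − 1` secondary
  eigenmodes survive spectral scaling.

The choice matters (see Limitations). After weight assignment the
recurrent matrix is rescaled so its spectral radius (largest absolute
eigenvalue) equals `ρ = 0.85` by default, the standard echo-state
guard; a zero/nilpotent matrix (e.g. `P1 = P2 = 0`) raises an error
rather than silently skipping the guard. Input weights are i.i.d.
uniform on (−0.1, 0.1). All randomness flows from one seeded generator
in a fixed order (module labels → pairs → magnitudes → signs → input
weights).

### Feature pipeline

EEG trials (trials × samples × channels, 128 Hz, 60 s in the reference
setting) are cropped into non-overlapping windows (6 s for the
valence/arousal tasks, 2 s for stress/calm; trailing remainders are
dropped; windows are half-open in 0-based samples). Each window is
L2-normalized **per channel** — inter-channel amplitude differences are
physiological signal, while overall amplitude is not. Each channel is
then summarized by the relative power of theta (4–8 Hz), alpha
(8–12 Hz), beta (12–30 Hz) and gamma (30–45 Hz): band energy is the
sum of squared one-sided DFT magnitudes over bins in `[low, high)`
(half-open, so adjacent bands never double-count an edge; no taper),
and each energy is divided by the channel's summed energy over the four
bands, so the four values per channel sum to exactly 1. The delta band
is excluded because the reference recordings are band-pass filtered to
4–45 Hz. A 32-channel window becomes a 4 × 32 = 128-vector, ordered
channel-major.

### Driving the reservoir with feature vectors

Window-level feature vectors are i.i.d. samples under the shuffled
cross-validation protocol, so carrying reservoir state across them
would leak information between folds. Each sample is therefore
presented for `steps_per_sample = 5` consecutive update steps from the
zero state, and the final state is that sample's representation
(per-sample encoding). A continuous mode (states collected along one
sequence after a washout) is used for memory capacity. Both counts are
configurable.

### Memory capacity

For delay `k`, a separate ridge readout (`λ = 1e−8`) is trained to
reconstruct `u(t − k)` from `x(t)` while the reservoir is driven by an
i.i.d. uniform(−1, 1) sequence (length 2000 by default, no per-sample
reset). The delay-`k` capacity is the squared Pearson correlation
between target and reconstruction, evaluated on the *held-out* last
30% of the usable steps (in-sample correlation is optimistically
biased; the split is a protocol choice). Total capacity truncates the
sum at `k_max` (200 by default; `2N` for linear bound checks). All
delays share a common time base starting at `max(washout, k_max)`.
For a linear reservoir of `N` units the total is bounded by `N`; a
shift-register reservoir attains ≈ `N − 1`, and both bounds are
enforced in tests.

### Experiment protocol

Ratings on the 1–9 scale are binarized: valence/arousal high iff the
rating exceeds 5; stress iff valence ≤ 3 and arousal ≥ 5; calm iff
4 ≤ valence ≤ 6 and arousal < 4, with all other records excluded from
the stress/calm task. The positive class is high/stress.

Phase I fixes `ρ = 0.85`, `α = 0.25` and exhaustively scores the
topology grid — `P1 ∈ {0.05, 0.1, 0.15, 0.2, 0.25, 0.3}`,
`M ∈ {1, 2, 3, 4, 5, 6, 8, 10}`, `P2 ∈ {P1/5, …, P1}`; 240 triples —
by 5-fold cross-validation repeated 3 times, drawing a fresh reservoir
per repeat (the repeat exists to average over initializations) and a
fresh fold partition per repeat; the cross-validation unit is the
window, not the trial or subject. The argmax is kept under strict
improvement, so ties resolve to the first triple in loop order.
Phase II fixes the winning topology and tunes `α` per task over
{0.1 … 0.5}. Accuracy, precision, sensitivity, specificity and F1 are
computed from the 2×2 confusion table; ratios with zero denominators
are reported as NaN with a flag rather than raised.

## Synthetic data

The generator emulates the *shape* of a DEAP-style session — 60 s
trials at 128 Hz over 32 channels with continuous 1–9 ratings — and the
one property the pipeline measures: class-dependent band power. Each
channel is a sum of four band-limited tones (frequency uniform inside
the band, random phase, redrawn per trial and channel) plus broadband
Gaussian noise; a trial's class multiplies chosen band amplitudes.
Ratings are drawn inside the rating region that makes the labelling
rule recover the generated class exactly, and an optional fraction of
trials falls in the stress/calm exclusion region.

Defaults (chosen once as a moderate-effect condition): unit base
amplitude, high class × 1.2 on beta and gamma, noise SD 3. At 200
trials (2,000 six-second windows) this yields cross-validated accuracy
near 0.9 — clearly above chance, below ceiling. What passing tests on
this generator do *not* show: robustness to 1/f spectra, artifacts,
inter-subject variability, or any spatial structure of real EEG; the
generator is a controlled oracle for the band-power pathway, not a
forward model.

A second fixture, `generate_separable_features`, builds two Gaussian
clusters directly on the band-power simplex (each channel's four
fractions non-negative, summing to 1) at a controlled centroid gap,
for fast readout and protocol tests that bypass the signal layer.

## Numerical choices

* Spectral radius via dense `numpy.linalg.eigvals`; the scaled matrix
  matches the target to 1e−8 relative.
* Ridge systems solved with `scipy.linalg.solve` (positive-definite
  path when `λ > 0`); a singular system at `λ = 0` raises with advice
  to use `λ > 0`. Default readout `λ = 1e−6`.
* Per-sample encoding is batched over samples (one matrix product per
  step), which makes the 2,000-sample × 600-unit experiments run in
  seconds on one CPU.
* Degree statistics use population (divide-by-N) variance; the
  coefficient of variation is signed and flagged unstable when
  |mean| < 1e−6 · SD.
* Experiment-scale defaults: N = 600, modular optimum (M = 6,
  P1 = 0.05, P2 = 0.02), basic baseline (M = 1, P1 = P2 = 0.05);
  memory-capacity sweeps use sequence length 2000, `k_max` 200,
  washout 100. These sizes keep the full suite and the reproduction
  script to a few minutes.

## Known limitations

* **Degree heterogeneity.** Under the default sign-balanced weights,
  the weighted in-degree mean of *both* the modular and the basic
  reservoir is a near-zero Gaussian, so the ratio of their CVs is
  heavy-tailed (Cauchy-like) and not a stable effect: the
  order-of-magnitude CV gap sometimes quoted for modular reservoirs is
  a property of single realizations, not of the construction. The
  package reports both binary and weighted degree modes so this can be
  inspected directly; the acceptance check encoding the ≥10× claim
  fails by design of the construction, and is kept as an honest
  negative result.
* **Memory capacity vs module count.** With sign-balanced weights the
  expected adjacency is zero, so modularity enters the spectrum only
  through the variance profile and the measured effect of `M` on MC at
  fixed `ρ` is within sampling noise (interior maximum at the default
  protocol, but small). Under `flip_one` the positive mean weight
  creates `M − 1` secondary eigenmodes and MC genuinely rises with
  `M`, at the cost of lower absolute capacity. Neither convention
  yields a pronounced rise-then-fall inside the default grid.
* The classification advantage of the modular topology on the
  synthetic dataset is small (≈ +0.002 mean accuracy, winning a
  majority of paired seeded repeats); the synthetic features are close
  to linearly separable, which leaves little room for topology to
  matter.
* Subject-wise or trial-wise cross-validation is available as an
  option but is not the reference protocol (which shuffles windows);
  window-level splitting is optimistic for real EEG.
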