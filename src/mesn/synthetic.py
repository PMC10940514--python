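"""Synthetic EEG-like data with controllable class-dependent band power.

The generator emulates the shape of a DEAP-style recording session —
trials of 60 s at 128 Hz over 32 channels with continuous 1–9
valence/arousal ratings — without any physiological realism beyond what
the band-power pipeline measures.  Each channel of a trial is a sum of
four band-limited oscillations (one per rhythm, with a frequency drawn
uniformly inside the band and a random phase, redrawn per trial and
channel) plus broadband Gaussian noise.  A trial's class scales the
amplitudes of chosen bands, so the relative band-power features carry a
class signal of known size, and ratings are emitted so that the task
labelling rules recover the generated class exactly.

Default condition: the high class raises beta and gamma amplitudes by a
factor 1.2 over a unit-amplitude baseline under broadband noise of
standard deviation 3 µV-equivalents — a moderate effect that keeps
classification well above chance but clearly below ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import DEFAULT_BANDS, TrialArray

__all__ = ["SyntheticSpec", "generate_trials", "generate_separable_features"]

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)

#: Moderate-effect default: the high class gains 20% beta/gamma amplitude.
DEFAULT_CLASS_EFFECTS = {
    0: {"theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
    1: {"theta": 1.0, "alpha": 1.0, "beta": 1.2, "gamma": 1.2},
}


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic recording session.

    ``class_effects`` maps class → per-band multiplicative amplitude
    factors; ``rating_rule`` chooses which labelling rule the emitted
    ratings are aligned with (``valence``, ``arousal`` or
    ``stress_calm``); ``excluded_fraction`` (stress_calm only) emits
    trials whose ratings match neither rule, exercising the exclusion
    branch downstream.
    """

    n_trials: int = 40
    channels: int = 32
    fs: float = 128.0
    trial_seconds: float = 60.0
    class_effects: dict = field(default_factory=lambda: DEFAULT_CLASS_EFFECTS)
    noise_sd: float = 3.0
    base_amplitude: float = 1.0
    rating_rule: str = "valence"
    excluded_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("need at least one trial")
        if self.rating_rule not in ("valence", "arousal", "stress_calm"):
            raise ConfigurationError(f"unknown rating rule {self.rating_rule!r}")
        if not 0.0 <= self.excluded_fraction < 1.0:
            raise ConfigurationError("excluded_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for cls, effects in self.class_effects.items():
            for band in BAND_NAMES:
                if effects.get(band, 1.0) <= 0:
                    raise ConfigurationError(
                        f"class {cls} has non-positive factor for band {band}"
                    )


def _ratings_for_class(
    cls: int, rule: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (valence, arousal) so the task rule recovers ``cls`` exactly."""
    if rule == "valence":
        v = rng.uniform(5.0, 9.0) if cls == 1 else rng.uniform(1.0, 5.0)
        # the high-valence rule is strict (> 5); keep a hair above
        v = np.nextafter(v, 9.0) if cls == 1 and v == 5.0 else v
        return float(v), float(rng.uniform(1.0, 9.0))
    if rule == "arousal":
        a = rng.uniform(5.0, 9.0) if cls == 1 else rng.uniform(1.0, 5.0)
        a = np.nextafter(a, 9.0) if cls == 1 and a == 5.0 else a
        return float(rng.uniform(1.0, 9.0)), float(a)
    # stress_calm
    if cls == 1:  # stress: valence <= 3 and arousal >= 5
        return float(rng.uniform(1.0, 3.0)), float(rng.uniform(5.0, 9.0))
    if cls == 0:  # calm: 4 <= valence <= 6 and arousal < 4
        return float(rng.uniform(4.0, 6.0)), float(rng.uniform(1.0, 3.9))
    # excluded: matches neither rule (valence too high for both)
    return float(rng.uniform(6.5, 9.0)), float(rng.uniform(4.0, 4.9))


def generate_trials(
    spec: SyntheticSpec,
) -> tuple[TrialArray, pd.DataFrame, np.ndarray]:
    """Generate trials, aligned ratings, and ground-truth classes.

    Classes alternate 0/1 over trials (balanced up to one trial) with a
    leading block of excluded trials (class −1) when
    ``excluded_fraction`` is positive, then the whole order is
    shuffled.  Returns ``(trials, ratings, classes)`` where ``ratings``
    has columns valence, arousal, dominance, liking.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    n_excluded = int(round(spec.excluded_fraction * n))
    classes = np.concatenate(
        [np.full(n_excluded, -1), np.arange(n - n_excluded) % 2]
    )
    classes = rng.permutation(classes)

    n_samples = int(round(spec.fs * spec.trial_seconds))
    t = np.arange(n_samples) / spec.fs
    data = np.empty((n, n_samples, spec.channels))
    for trial in range(n):
        cls = int(classes[trial])
        effects = spec.class_effects.get(cls, spec.class_effects.get(0, {}))
        signal = np.zeros((n_samples, spec.channels))
        for band in DEFAULT_BANDS:
            amp = spec.base_amplitude * effects.get(band.name, 1.0)
            freqs = rng.uniform(band.low, band.high, size=spec.channels)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.channels)
            signal += amp * np.sin(
                2.0 * np.pi * freqs[None, :] * t[:, None] + phases[None, :]
            )
        if spec.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, spec.noise_sd, size=(n_samples, spec.channels)
            )
        data[trial] = signal

    rating_rows = []
    for cls in classes:
        v, a = _ratings_for_class(int(cls), spec.rating_rule, rng)
        rating_rows.append(
            {
                "valence": v,
                "arousal": a,
                "dominance": float(rng.uniform(1.0, 9.0)),
                "liking": float(rng.uniform(1.0, 9.0)),
            }
        )
    ratings = pd.DataFrame(rating_rows)
    trials = TrialArray(data=data, fs=spec.fs, trial_seconds=spec.trial_seconds)
    return trials, ratings, classes


def generate_separable_features(
    n_per_class: int,
    dim: int = 128,
    gap: float = 1.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian clusters living on the band-power simplex.

    Builds valid relative-band-power vectors (each consecutive block of
    four entries is nonnegative and sums to one) whose class centroids
    are ``gap`` apart in Euclidean distance, by shifting mass between
    two bands of every channel block and renormalizing after noise.
    Fast fixture for readout and protocol tests that bypasses the
    signal layer.
    """
    if gap < 0:
        raise ConfigurationError("gap must be nonnegative")
    if dim % 4 != 0:
        raise ConfigurationError(f"feature dimension must be a multiple of 4, got {dim}")
    rng = np.random.default_rng(seed)
    quads = dim // 4
    base = np.full(dim, 0.25)
    delta = np.zeros(dim)
    # move mass from band 0 to band 2 within every channel block
    if gap > 0:
        step = gap / np.sqrt(2.0 * quads)
        delta[0::4] = -step
        delta[2::4] = step
    centers = {0: base - delta / 2.0, 1: base + delta / 2.0}

    labels = np.repeat([0, 1], n_per_class)
    labels = rng.permutation(labels)
    feats = np.empty((labels.shape[0], dim))
    for i, cls in enumerate(labels):
        x = centers[int(cls)] + rng.normal(0.0, noise_sd, size=dim)
        x = np.clip(x, 1e-9, None)
        x = x.reshape(quads, 4)
        x = x / x.sum(axis=1, keepdims=True)
        feats[i] = x.ravel()
    return feats, labels
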