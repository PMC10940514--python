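"""EEG band-power feature extraction.

Raw multichannel trials are cropped into non-overlapping windows, each
window is L2-normalized per channel, and each channel's spectrum is
summarized by the relative power of four rhythms:

    theta 4–8 Hz, alpha 8–12 Hz, beta 12–30 Hz, gamma 30–45 Hz.

The delta band is excluded (DEAP's distributed signals are band-pass
filtered to 4–45 Hz, so there is no delta content to measure).  Band
energy is the sum of squared DFT magnitudes over the bins falling in
the band, taken half-open ``[low, high)`` so adjacent bands never
double-count a shared edge; relative power divides each band's energy
by the summed energy of the four retained bands, so the four values per
channel always sum to one.  A 32-channel segment therefore becomes a
4 × 32 = 128-dimensional feature vector, ordered channel-major
(channel 0's theta/alpha/beta/gamma, then channel 1's, ...).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateSignalError,
    EmptyBandError,
    InvalidWindowError,
    ShapeError,
    ZeroNormError,
)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "TrialArray",
    "crop_trials",
    "l2_normalize",
    "band_energy",
    "extract_features",
    "extract_features_batch",
    "features_to_frame",
    "load_deap_subject",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open on [low, high) Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(
                f"band {self.name!r} needs low < high, got [{self.low}, {self.high})"
            )


#: The four retained rhythms, in feature order.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass
class TrialArray:
    """A stack of trials: (trials, samples, channels) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    trial_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError(
                f"trial data must be (trials, samples, channels), got {self.data.shape}"
            )
        expected = int(round(self.fs * self.trial_seconds))
        if self.data.shape[1] != expected:
            raise ShapeError(
                f"trials have {self.data.shape[1]} samples but fs*seconds = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def crop_trials(
    trials: TrialArray, window_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Crop every trial into non-overlapping windows.

    Segment ``k`` of a trial covers samples ``[k*w, (k+1)*w)`` with
    ``w = window_seconds * fs``; a trailing remainder shorter than the
    window is dropped.

    Returns ``(segments, trial_index)`` with segments shaped
    (n_segments, w, channels) and ``trial_index`` giving each segment's
    trial of origin.
    """
    w = int(round(window_seconds * trials.fs))
    n_samples = trials.data.shape[1]
    if w < 1 or w > n_samples:
        raise InvalidWindowError(
            f"window of {window_seconds} s ({w} samples) does not fit a "
            f"{n_samples}-sample trial"
        )
    per_trial = n_samples // w
    clipped = trials.data[:, : per_trial * w, :]
    segments = clipped.reshape(trials.n_trials, per_trial, w, trials.n_channels)
    segments = segments.reshape(-1, w, trials.n_channels)
    trial_index = np.repeat(np.arange(trials.n_trials), per_trial)
    return segments, trial_index


def l2_normalize(segment: np.ndarray) -> np.ndarray:
    """Scale each channel of a (samples, channels) segment to unit norm."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 1:
        seg = seg[:, None]
    norms = np.linalg.norm(seg, axis=0)
    if np.any(norms == 0):
        raise ZeroNormError("a channel with zero norm cannot be L2-normalized")
    return seg / norms


def _band_mask(n_samples: int, fs: float, band: BandDefinition) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return (freqs >= band.low) & (freqs < band.high)


def band_energy(channel_signal: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Spectral energy of one channel in one band.

    Sum of squared one-sided DFT magnitudes over bins with frequency in
    ``[low, high)``.  No window taper is applied.  The one-sided sum is
    used without conjugate-symmetry doubling; relative band powers are
    unaffected by that constant.
    """
    sig = np.asarray(channel_signal, dtype=float).ravel()
    mask = _band_mask(sig.shape[0], fs, band)
    if not mask.any():
        raise EmptyBandError(
            f"band {band.name!r} [{band.low}, {band.high}) Hz contains no DFT "
            f"bins for {sig.shape[0]} samples at {fs} Hz"
        )
    spectrum = np.fft.rfft(sig)
    return float(np.sum(np.abs(spectrum[mask]) ** 2))


def extract_features(
    segment: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Relative band powers of one (samples, channels) segment.

    The segment is L2-normalized per channel, each channel's energy is
    computed per band, and each energy is divided by that channel's
    summed energy across the given bands.  Returns a length
    ``len(bands) * channels`` vector, channel-major.
    """
    return extract_features_batch(np.asarray(segment)[None, ...], fs, bands)[0]


def extract_features_batch(
    segments: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Vectorized :func:`extract_features` over (n, samples, channels)."""
    segs = np.asarray(segments, dtype=float)
    if segs.ndim != 3:
        raise ShapeError(
            f"expected (segments, samples, channels), got shape {segs.shape}"
        )
    n, w, c = segs.shape
    norms = np.linalg.norm(segs, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ZeroNormError("a channel with zero norm cannot be L2-normalized")
    segs = segs / norms
    spectra = np.fft.rfft(segs, axis=1)
    power = np.abs(spectra) ** 2  # (n, bins, c)
    energies = np.empty((n, len(bands), c))
    for b, band in enumerate(bands):
        mask = _band_mask(w, fs, band)
        if not mask.any():
            raise EmptyBandError(
                f"band {band.name!r} contains no DFT bins for {w} samples at {fs} Hz"
            )
        energies[:, b, :] = power[:, mask, :].sum(axis=1)
    totals = energies.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise DegenerateSignalError(
            "a channel has zero energy in every retained band"
        )
    rel = energies / totals  # (n, bands, c)
    # channel-major: channel 0's bands first
    return rel.transpose(0, 2, 1).reshape(n, c * len(bands))


def features_to_frame(
    features: np.ndarray,
    trial_index: np.ndarray | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Tidy DataFrame of a feature matrix (segment_id, trial_id, columns)."""
    features = np.atleast_2d(features)
    n, dim = features.shape
    c = dim // len(bands)
    cols = [f"ch{ch:02d}_{band.name}" for ch in range(c) for band in bands]
    frame = pd.DataFrame(features, columns=cols)
    frame.insert(0, "segment_id", np.arange(n))
    frame.insert(
        1,
        "trial_id",
        np.asarray(trial_index) if trial_index is not None else np.full(n, -1),
    )
    return frame


def load_deap_subject(
    path, n_eeg_channels: int = 32, fs: float = 128.0
) -> tuple[TrialArray, pd.DataFrame]:
    """Read one DEAP preprocessed per-subject file.

    Accepts the pickled-dict distribution (``data`` shaped
    trials × channels × samples, ``labels`` shaped trials × 4 with
    columns valence, arousal, dominance, liking) or an ``.npz`` with
    the same keys.  Both sample-count variants are handled: 8064
    samples (63 s including the 3-s pre-trial baseline, which is
    removed here) and 7680 samples (60 s, baseline already removed).
    Only the first ``n_eeg_channels`` channels are kept.
    """
    path = Path(path)
    if path.suffix == ".npz":
        archive = np.load(path, allow_pickle=False)
        data, labels = archive["data"], archive["labels"]
    else:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
        data, labels = payload["data"], payload["labels"]
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ShapeError(f"expected trials × channels × samples, got {data.shape}")
    data = data[:, :n_eeg_channels, :]
    n_samples = data.shape[2]
    baseline = int(round(3 * fs))
    if n_samples == int(round(63 * fs)):
        data = data[:, :, baseline:]
    elif n_samples != int(round(60 * fs)):
        raise ShapeError(
            f"unexpected trial length {n_samples}; expected {int(63 * fs)} "
            f"(with baseline) or {int(60 * fs)} (baseline removed)"
        )
    trials = TrialArray(
        data=np.transpose(data, (0, 2, 1)), fs=fs, trial_seconds=60.0
    )
    ratings = pd.DataFrame(
        np.asarray(labels, dtype=float)[:, :4],
        columns=["valence", "arousal", "dominance", "liking"],
    )
    return trials, ratings
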