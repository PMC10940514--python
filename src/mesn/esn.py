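"""Leaky-integrator echo state network: dynamics, readout, prediction.

The reservoir state evolves as

    x(t+1) = (1 - alpha) x(t) + alpha f(W_in u(t) + W_rc x(t))

with leak rate ``alpha`` in [0, 1] and activation ``f`` (tanh by
default; identity is available for linear memory-capacity analyses).
Only the linear readout is trained, by ridge regression:

    W_out = Y Xᵀ (X Xᵀ + lambda I)⁻¹

where the columns of ``X`` are collected reservoir states and the
columns of ``Y`` the matching targets.  Prediction is ``y = W_out x``
with hard labels by argmax (ties resolved toward the lower class
index).

Two encoding regimes are supported:

* per-sample (``reset_per_sample=True``): each input vector is
  presented ``steps_per_sample`` consecutive steps from the zero state
  and the final state is kept — one state column per sample.  This is
  the regime for classifying independently shuffled feature segments,
  where carrying state across samples would leak information between
  cross-validation folds.
* continuous (``reset_per_sample=False``): the input rows form one time
  series; every post-washout state is kept.  This is the regime for
  memory-capacity evaluation.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Callable, NamedTuple

import numpy as np
import scipy.linalg

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    ShapeError,
    SingularSystemError,
)
from .topology import ReservoirMatrices, TopologyConfig

__all__ = [
    "ESNConfig",
    "StateMatrix",
    "ESNModel",
    "update_state",
    "encode_sequence",
    "fit_readout",
    "predict",
    "one_hot",
    "train_classifier",
    "save_model",
    "load_model",
]

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    "identity": lambda z: z,
}


@dataclass(frozen=True)
class ESNConfig:
    """Hyper-parameters of the ESN dynamics and readout.

    Parameters
    ----------
    alpha : float
        Leak rate in [0, 1]; 0.25 for the valence and stress/calm
        tasks, 0.3 for arousal.
    rho_target : float
        Spectral-radius target for the recurrent matrix (default 0.85).
    ridge_lambda : float
        Ridge penalty ``lambda >= 0`` of the readout fit.
    washout : int
        Steps discarded at the start of continuous encoding.
    steps_per_sample : int
        Presentations of each input vector in per-sample encoding.
    reset_per_sample : bool
        Choose per-sample (True) or continuous (False) encoding.
    activation : {"tanh", "identity"}
        Reservoir nonlinearity.
    input_scale : float
        Half-range of the uniform input weights.
    seed : int
        Seed forwarded to reservoir generation by the experiment layer.
    """

    alpha: float = 0.25
    rho_target: float = 0.85
    ridge_lambda: float = 1e-6
    washout: int = 0
    steps_per_sample: int = 5
    reset_per_sample: bool = True
    activation: str = "tanh"
    input_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"leak rate must lie in [0, 1], got {self.alpha}")
        if self.ridge_lambda < 0:
            raise ConfigurationError(
                f"ridge penalty must be nonnegative, got {self.ridge_lambda}"
            )
        if self.washout < 0:
            raise ConfigurationError(f"washout must be nonnegative, got {self.washout}")
        if self.steps_per_sample < 1:
            raise ConfigurationError(
                f"steps_per_sample must be positive, got {self.steps_per_sample}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(_ACTIVATIONS)}"
            )

    @property
    def activation_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return _ACTIVATIONS[self.activation]


class StateMatrix(NamedTuple):
    """Collected reservoir states and aligned targets (columns = time)."""

    x: np.ndarray  # (N, T)
    y: np.ndarray  # (K, T)


def update_state(
    x: np.ndarray,
    u: np.ndarray,
    mats: ReservoirMatrices,
    alpha: float,
    activation: Callable[[np.ndarray], np.ndarray] = np.tanh,
) -> np.ndarray:
    """One leaky-integrator step: (1-a)x + a·f(W_in u + W_rc x).

    ``x`` may be a single state vector of length N or an (N, B) batch.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    n = mats.w_rc.shape[0]
    if x.shape[0] != n:
        raise ShapeError(f"state has length {x.shape[0]}, reservoir expects {n}")
    if u.shape[0] != mats.w_in.shape[1]:
        raise ShapeError(
            f"input has length {u.shape[0]}, reservoir expects {mats.w_in.shape[1]}"
        )
    return (1.0 - alpha) * x + alpha * activation(mats.w_in @ u + mats.w_rc @ x)


def encode_sequence(
    inputs: np.ndarray, mats: ReservoirMatrices, config: ESNConfig
) -> np.ndarray:
    """Drive the reservoir over a (T, D) input array; return state columns.

    Per-sample mode returns one column per input row (the state after
    ``steps_per_sample`` presentations from zero); continuous mode
    returns the post-washout trajectory, one column per kept step.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.size == 0:
        raise EmptyInputError("cannot encode an empty input sequence")
    t, d = inputs.shape
    if d != mats.w_in.shape[1]:
        raise ShapeError(
            f"inputs have {d} features, reservoir expects {mats.w_in.shape[1]}"
        )
    f = config.activation_fn
    alpha = config.alpha
    if config.reset_per_sample:
        # batched over samples: every column starts from the zero state
        drive = mats.w_in @ inputs.T  # (N, T), constant per sample
        x = np.zeros((mats.n, t))
        for _ in range(config.steps_per_sample):
            x = (1.0 - alpha) * x + alpha * f(drive + mats.w_rc @ x)
        return x
    if t <= config.washout:
        raise EmptyInputError(
            f"sequence length {t} does not exceed washout {config.washout}"
        )
    x = np.zeros(mats.n)
    kept = np.empty((mats.n, t - config.washout))
    for step in range(t):
        x = (1.0 - alpha) * x + alpha * f(mats.w_in @ inputs[step] + mats.w_rc @ x)
        if step >= config.washout:
            kept[:, step - config.washout] = x
    return kept


def fit_readout(
    states: np.ndarray, targets: np.ndarray, ridge_lambda: float
) -> np.ndarray:
    """Ridge-regression readout: W = Y Xᵀ (X Xᵀ + lambda I)⁻¹.

    ``states`` is (N, T), ``targets`` is (K, T) (a 1-D target is
    treated as K = 1).  Returns the (K, N) readout matrix.

    Raises :class:`SingularSystemError` when the system is singular,
    which at ``lambda = 0`` signals that a positive penalty is needed.
    """
    x = np.atleast_2d(np.asarray(states, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if x.size == 0:
        raise EmptyInputError("cannot fit a readout on an empty state matrix")
    if x.shape[1] != y.shape[1]:
        raise ShapeError(
            f"states have {x.shape[1]} columns but targets have {y.shape[1]}"
        )
    if ridge_lambda < 0:
        raise ConfigurationError(f"ridge penalty must be nonnegative, got {ridge_lambda}")
    gram = x @ x.T
    gram[np.diag_indices_from(gram)] += ridge_lambda
    rhs = x @ y.T  # (N, K)
    try:
        if ridge_lambda > 0:
            w = scipy.linalg.solve(gram, rhs, assume_a="pos")
        else:
            w = scipy.linalg.solve(gram, rhs)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise SingularSystemError(
            "state covariance is singular; use ridge_lambda > 0"
        ) from None
    if not np.all(np.isfinite(w)):
        raise SingularSystemError(
            "readout solve produced non-finite weights; use ridge_lambda > 0"
        )
    return w.T


def predict(
    weights: np.ndarray, states: np.ndarray, return_labels: bool = True
) -> tuple[np.ndarray, np.ndarray] | np.ndarray:
    """Readout scores ``W x`` per state column, plus argmax labels.

    Ties in the argmax resolve toward the lower class index
    (``np.argmax`` convention), so an all-zero score column yields
    label 0.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    x = np.atleast_2d(np.asarray(states, dtype=float))
    if w.shape[1] != x.shape[0]:
        raise ShapeError(
            f"readout expects states of length {w.shape[1]}, got {x.shape[0]}"
        )
    scores = w @ x
    if not return_labels:
        return scores
    return scores, np.argmax(scores, axis=0)


def one_hot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """(K, T) one-hot target matrix with {0, 1} coding."""
    labels = np.asarray(labels, dtype=int)
    k = int(labels.max()) + 1 if n_classes is None else n_classes
    out = np.zeros((k, labels.shape[0]))
    out[labels, np.arange(labels.shape[0])] = 1.0
    return out


# ---------------------------------------------------------------------------
# Trained-model container and persistence
# ---------------------------------------------------------------------------


@dataclass
class ESNModel:
    """A reservoir, its ESN configuration, and a fitted readout."""

    mats: ReservoirMatrices
    config: ESNConfig
    w_out: np.ndarray
    classes: np.ndarray

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scores and class labels for a (T, D) feature array."""
        states = encode_sequence(features, self.mats, self.config)
        scores, idx = predict(self.w_out, states)
        return scores, self.classes[idx]


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    mats: ReservoirMatrices,
    config: ESNConfig,
) -> ESNModel:
    """Encode features, fit the one-hot ridge readout, return the model."""
    labels = np.asarray(labels)
    classes, encoded = np.unique(labels, return_inverse=True)
    states = encode_sequence(features, mats, config)
    y = one_hot(encoded, n_classes=classes.shape[0])
    w_out = fit_readout(states, y, config.ridge_lambda)
    return ESNModel(mats=mats, config=config, w_out=w_out, classes=classes)


def save_model(model: ESNModel, path) -> None:
    """Write a trained model to a compressed archive (lossless)."""
    meta = {
        "esn_config": asdict(model.config),
        "rho_target": model.mats.rho_target,
        "topology_config": asdict(model.mats.config)
        if model.mats.config is not None
        else None,
    }
    arrays = {
        "w_rc": model.mats.w_rc,
        "w_in": model.mats.w_in,
        "w_out": model.w_out,
        "classes": model.classes,
    }
    if model.mats.labels is not None:
        arrays["labels"] = model.mats.labels
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2))


def load_model(path) -> ESNModel:
    """Read a model archive written by :func:`save_model`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {
            name[:-4]: np.load(io.BytesIO(zf.read(name)))
            for name in zf.namelist()
            if name.endswith(".npy")
        }
    topo = None
    if meta.get("topology_config") is not None:
        topo = TopologyConfig(**meta["topology_config"])
    mats = ReservoirMatrices(
        w_rc=arrays["w_rc"],
        w_in=arrays["w_in"],
        rho_target=float(meta["rho_target"]),
        labels=arrays.get("labels"),
        config=topo,
    )
    return ESNModel(
        mats=mats,
        config=ESNConfig(**meta["esn_config"]),
        w_out=arrays["w_out"],
        classes=arrays["classes"],
    )
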