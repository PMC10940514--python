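"""Modular reservoir topology generation.

A modular echo state network (M-ESN) replaces the Erdős–Rényi reservoir
of a basic ESN with a community-structured random graph controlled by
three parameters:

``M``
    number of modules (communities) the ``N`` reservoir neurons are
    partitioned into;
``P1``
    probability that an unordered pair of neurons in the *same* module
    is connected;
``P2``
    probability that an unordered pair of neurons in *different*
    modules is connected, with ``P2 <= P1`` (inter-community wiring is
    sparser than intra-community wiring, as in cortical networks).

With ``M = 1``, or with ``P1 = P2``, the construction degenerates to an
ordinary Erdős–Rényi reservoir — the "basic ESN" baseline.

Connections are bidirectional: every sampled pair ``{i, j}`` yields both
directed weights ``W[i, j]`` and ``W[j, i]``, with independent
magnitudes drawn from a standard normal truncated to ``(0, 1)`` and a
sign rule under which roughly half of all pairs carry opposite signs in
the two directions.  Under the default ``symmetric`` rule every entry
is sign-balanced: each pair draws one shared random sign and, with
probability 1/2, one randomly chosen direction is negated, so the
expected weight matrix is zero.  The alternative ``flip_one`` rule
keeps the base weights positive (only the opposite-signed pairs carry
a negative direction); the resulting positive mean weight gives the
modular graph a block-structured expected adjacency with ``M - 1``
secondary eigenmodes.  The recurrent matrix is then rescaled so its
spectral radius (largest absolute eigenvalue) equals a target
``rho <= 1``, the standard echo-state-property guard.

Randomness is consumed from a single seeded generator in a fixed order
(module labels → pair sampling → weight magnitudes → signs → input
weights), so every intermediate product is individually reproducible.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateReservoirError, ShapeError

__all__ = [
    "TopologyConfig",
    "ReservoirTopology",
    "ReservoirMatrices",
    "assign_modules",
    "sample_pairs",
    "assign_weights",
    "scale_spectral_radius",
    "spectral_radius",
    "generate_input_weights",
    "generate_reservoir",
    "save_reservoir",
    "load_reservoir",
]

#: Default reservoir size used throughout the experiments.
DEFAULT_N = 600
#: Default spectral-radius target (echo-state-property guard).
DEFAULT_RHO = 0.85
#: Default input-weight half-range: entries uniform on (-0.1, 0.1).
DEFAULT_INPUT_SCALE = 0.1

WeightDist = Literal["truncnorm", "uniform"]
SignRule = Literal["flip_one", "symmetric"]


@dataclass(frozen=True)
class TopologyConfig:
    """Parameters of the modular reservoir graph.

    Parameters
    ----------
    n : int
        Reservoir size (number of neurons). Default 600.
    modules : int
        Module count ``M``; ``1 <= M <= n``. ``M = 1`` gives an
        unpartitioned (basic) reservoir.
    p_intra : float
        ``P1``, intra-module pair connection probability, in [0, 1].
    p_inter : float
        ``P2``, inter-module pair connection probability, in [0, 1];
        must not exceed ``p_intra`` unless ``allow_p2_greater``.
    seed : int
        Seed of the single generator driving every random choice.
    weight_dist : {"truncnorm", "uniform"}
        Distribution of weight magnitudes on (0, 1).
    sign_rule : {"symmetric", "flip_one"}
        ``symmetric`` (default): each pair shares one random sign and
        with probability 1/2 one randomly chosen direction is negated,
        so every entry is sign-balanced.  ``flip_one``: base weights
        stay positive apart from the flipped direction of the
        opposite-signed pairs, leaving a positive mean weight.
    allow_p2_greater : bool
        If true, ``p_inter > p_intra`` produces a warning instead of a
        :class:`ConfigurationError`.
    """

    n: int = DEFAULT_N
    modules: int = 6
    p_intra: float = 0.05
    p_inter: float = 0.02
    seed: int = 0
    weight_dist: WeightDist = "truncnorm"
    sign_rule: SignRule = "symmetric"
    allow_p2_greater: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"reservoir size must be positive, got n={self.n}")
        if not 1 <= self.modules <= self.n:
            raise ConfigurationError(
                f"module count must satisfy 1 <= M <= N, got M={self.modules}, N={self.n}"
            )
        for name, p in (("p_intra", self.p_intra), ("p_inter", self.p_inter)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.p_inter > self.p_intra:
            msg = (
                f"p_inter={self.p_inter} exceeds p_intra={self.p_intra}; "
                "inter-community wiring is expected to be the sparser one"
            )
            if self.allow_p2_greater:
                warnings.warn(msg, stacklevel=3)
            else:
                raise ConfigurationError(msg)
        if self.weight_dist not in ("truncnorm", "uniform"):
            raise ConfigurationError(f"unknown weight_dist {self.weight_dist!r}")
        if self.sign_rule not in ("flip_one", "symmetric"):
            raise ConfigurationError(f"unknown sign_rule {self.sign_rule!r}")


@dataclass(frozen=True)
class ReservoirTopology:
    """Module assignment plus the sampled set of connected pairs.

    ``pairs`` is an ``(E, 2)`` integer array of unordered pairs stored
    with ``i < j``; each pair appears at most once and never on the
    diagonal.
    """

    labels: np.ndarray
    pairs: np.ndarray

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def intra_mask(self) -> np.ndarray:
        """Boolean mask over ``pairs``: True where both ends share a module."""
        return self.labels[self.pairs[:, 0]] == self.labels[self.pairs[:, 1]]


@dataclass
class ReservoirMatrices:
    """Recurrent and input weight matrices of a generated reservoir.

    Attributes
    ----------
    w_rc : (N, N) ndarray
        Recurrent weights, scaled so the largest absolute eigenvalue
        equals ``rho_target``.  Structurally symmetric: ``w_rc[i, j]``
        is nonzero iff ``w_rc[j, i]`` is, with independent values.
    w_in : (N, D) ndarray
        Input weights, i.i.d. uniform on (-input_scale, input_scale).
    rho_target : float
        Spectral radius after scaling.
    labels : ndarray or None
        Module assignment, kept for heterogeneity analyses and export.
    config : TopologyConfig or None
        The configuration that produced the matrices, when generated
        through :func:`generate_reservoir`.
    """

    w_rc: np.ndarray
    w_in: np.ndarray
    rho_target: float
    labels: np.ndarray | None = None
    config: TopologyConfig | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.w_rc.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]


def assign_modules(n: int, modules: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly assign ``n`` neurons to ``modules`` balanced clusters.

    The assignment is balanced — module sizes differ by at most one —
    and then randomly permuted, so which neurons land in which module
    is uniform while the size profile is deterministic.

    Returns a length-``n`` integer array of labels in ``{0..modules-1}``.
    """
    if modules < 1 or modules > n:
        raise ConfigurationError(
            f"module count must satisfy 1 <= M <= N, got M={modules}, N={n}"
        )
    base = np.arange(n) % modules
    return rng.permutation(base)


def sample_pairs(
    labels: np.ndarray,
    p_intra: float,
    p_inter: float,
    rng: np.random.Generator,
    *,
    allow_p2_greater: bool = False,
) -> np.ndarray:
    """Sample the unordered connected pairs of the modular graph.

    Each same-module pair is included independently with probability
    ``p_intra``; each cross-module pair with probability ``p_inter``.
    Self-pairs are never produced.

    Returns an ``(E, 2)`` integer array with ``i < j`` per row.
    """
    if p_inter > p_intra:
        msg = f"p_inter={p_inter} exceeds p_intra={p_intra}"
        if allow_p2_greater:
            warnings.warn(msg, stacklevel=2)
        else:
            raise ConfigurationError(msg)
    labels = np.asarray(labels)
    n = labels.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    probs = np.where(same, p_intra, p_inter)
    keep = rng.random(iu.shape[0]) < probs
    return np.column_stack((iu[keep], ju[keep]))


def _magnitudes(size: int, dist: WeightDist, rng: np.random.Generator) -> np.ndarray:
    if dist == "truncnorm":
        # standard normal conditioned on (0, 1)
        return stats.truncnorm.rvs(0.0, 1.0, size=size, random_state=rng)
    return rng.uniform(0.0, 1.0, size=size)


def assign_weights(
    pairs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    *,
    weight_dist: WeightDist = "truncnorm",
    sign_rule: SignRule = "symmetric",
) -> np.ndarray:
    """Turn a pair set into an unscaled signed recurrent weight matrix.

    Every pair ``{i, j}`` becomes a bidirectional connection: both
    ``W[i, j]`` and ``W[j, i]`` are nonzero, with independent magnitudes
    on (0, 1).  With probability 1/2 a pair is made *opposite-signed*
    by negating one randomly chosen direction, so about half of all
    pairs carry opposite signs in their two directions.  Under the
    default ``symmetric`` rule the base sign of each pair is itself
    uniformly random (zero mean weight); under ``flip_one`` the
    remaining pairs stay positive in both directions (positive mean
    weight, block-structured expected adjacency).

    All non-pair entries are exactly zero; the diagonal is zero.
    """
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    w = np.zeros((n, n))
    e = pairs.shape[0]
    if e == 0:
        return w
    if pairs.min() < 0 or pairs.max() >= n:
        raise ShapeError(f"pair indices out of range for N={n}")

    mag_fwd = _magnitudes(e, weight_dist, rng)
    mag_bwd = _magnitudes(e, weight_dist, rng)
    shared = rng.integers(0, 2, size=e) * 2 - 1  # ±1 per pair
    opposite = rng.random(e) < 0.5
    flip_fwd = rng.integers(0, 2, size=e).astype(bool)  # which direction flips

    if sign_rule == "flip_one":
        base = np.ones(e)
    elif sign_rule == "symmetric":
        base = shared.astype(float)
    else:
        raise ConfigurationError(f"unknown sign_rule {sign_rule!r}")
    sign_fwd = base.copy()
    sign_bwd = base.copy()
    sign_fwd[opposite & flip_fwd] *= -1.0
    sign_bwd[opposite & ~flip_fwd] *= -1.0

    i, j = pairs[:, 0], pairs[:, 1]
    w[i, j] = sign_fwd * mag_fwd
    w[j, i] = sign_bwd * mag_bwd
    return w


def spectral_radius(w: np.ndarray) -> float:
    """Largest absolute eigenvalue of ``w``."""
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {w.shape}")
    if w.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(w))))


def scale_spectral_radius(w: np.ndarray, rho_target: float) -> np.ndarray:
    """Rescale ``w`` so its spectral radius equals ``rho_target``.

    Raises :class:`DegenerateReservoirError` when the spectral radius of
    ``w`` is zero (zero or nilpotent matrix), because no rescaling can
    reach a positive target and the echo-state guard would be
    meaningless.
    """
    if rho_target <= 0:
        raise ConfigurationError(f"rho_target must be positive, got {rho_target}")
    rho = spectral_radius(w)
    if rho == 0.0:
        raise DegenerateReservoirError(
            "unscaled recurrent matrix has spectral radius 0 "
            "(zero or nilpotent); cannot scale to a positive target"
        )
    return w * (rho_target / rho)


def generate_input_weights(
    n: int, n_inputs: int, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Input weight matrix with entries i.i.d. uniform on (-scale, scale)."""
    if scale <= 0:
        raise ConfigurationError(f"input scale must be positive, got {scale}")
    return rng.uniform(-scale, scale, size=(n, n_inputs))


def generate_reservoir(
    config: TopologyConfig,
    rho_target: float = DEFAULT_RHO,
    n_inputs: int = 128,
    input_scale: float = DEFAULT_INPUT_SCALE,
) -> ReservoirMatrices:
    """Generate a complete modular reservoir from a configuration.

    Composes :func:`assign_modules`, :func:`sample_pairs`,
    :func:`assign_weights`, :func:`scale_spectral_radius` and
    :func:`generate_input_weights` on one seeded generator, in that
    order.  Identical configurations produce bit-identical matrices.

    Raises
    ------
    DegenerateReservoirError
        If the sampled graph yields spectral radius zero (for example
        ``p_intra = p_inter = 0``).
    """
    rng = np.random.default_rng(config.seed)
    labels = assign_modules(config.n, config.modules, rng)
    pairs = sample_pairs(
        labels,
        config.p_intra,
        config.p_inter,
        rng,
        allow_p2_greater=True,  # config already validated / warned
    )
    w = assign_weights(
        pairs, config.n, rng, weight_dist=config.weight_dist, sign_rule=config.sign_rule
    )
    w = scale_spectral_radius(w, rho_target)
    w_in = generate_input_weights(config.n, n_inputs, input_scale, rng)
    return ReservoirMatrices(
        w_rc=w, w_in=w_in, rho_target=float(rho_target), labels=labels, config=config
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_reservoir(mats: ReservoirMatrices, path) -> None:
    """Write a reservoir to a compressed archive (lossless round trip).

    The archive is a zip file holding ``w_rc.npy``, ``w_in.npy``,
    ``labels.npy`` and a JSON document with the spectral-radius target
    and the full :class:`TopologyConfig`.
    """
    meta = {
        "format_version": _ARCHIVE_VERSION,
        "rho_target": mats.rho_target,
        "config": asdict(mats.config) if mats.config is not None else None,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, arr in (("w_rc", mats.w_rc), ("w_in", mats.w_in)):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())
        if mats.labels is not None:
            buf = io.BytesIO()
            np.save(buf, np.asarray(mats.labels))
            zf.writestr("labels.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2))


def load_reservoir(path) -> ReservoirMatrices:
    """Read a reservoir archive written by :func:`save_reservoir`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        w_rc = np.load(io.BytesIO(zf.read("w_rc.npy")))
        w_in = np.load(io.BytesIO(zf.read("w_in.npy")))
        labels = None
        if "labels.npy" in zf.namelist():
            labels = np.load(io.BytesIO(zf.read("labels.npy")))
    config = None
    if meta.get("config") is not None:
        config = TopologyConfig(**meta["config"])
    return ReservoirMatrices(
        w_rc=w_rc,
        w_in=w_in,
        rho_target=float(meta["rho_target"]),
        labels=labels,
        config=config,
    )
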