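"""Reservoir memory capacity.

Memory capacity measures how much of an i.i.d. input sequence's past a
reservoir can linearly reconstruct from its current state.  For delay
``k`` a separate linear readout ``w_k`` is trained to output
``u(t - k)`` from ``x(t)``; the delay-``k`` capacity is the squared
Pearson correlation

    MC_k = cov²(u(t-k), y_k(t)) / (var(u(t)) · var(y_k(t)))

and the total capacity is the sum over delays, truncated at ``k_max``.
For a linear (identity-activation) reservoir of ``N`` units the total
is bounded above by ``N``.

Protocol choices: the input is i.i.d. uniform on (−1, 1); readouts are
fitted on the earlier ``train_fraction`` of the usable time steps and
the correlations are evaluated on the held-out remainder, which avoids
the optimistic bias of in-sample correlation; delays share a common
time base starting at ``max(washout, k_max)`` so every probed delay has
a valid target at every used step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .esn import ESNConfig, encode_sequence
from .exceptions import ConfigurationError, DegenerateReservoirError
from .topology import ReservoirMatrices, TopologyConfig, generate_reservoir

__all__ = ["MCConfig", "MCResult", "estimate_mc", "mc_parameter_sweep"]

logger = logging.getLogger(__name__)

#: Ridge penalty for the per-delay readouts; tiny, to tame
#: near-singular state covariances without biasing the reconstruction.
MC_RIDGE_LAMBDA = 1e-8


@dataclass(frozen=True)
class MCConfig:
    """Protocol parameters of a memory-capacity run."""

    length: int = 2000
    k_max: int = 200
    washout: int = 100
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.k_max < 1:
            raise ConfigurationError(f"k_max must be positive, got {self.k_max}")
        if self.k_max >= self.length * (1.0 - self.train_fraction):
            raise ConfigurationError(
                f"k_max={self.k_max} leaves no held-out data at length "
                f"{self.length}, train_fraction {self.train_fraction}"
            )
        if self.washout >= self.length * self.train_fraction:
            raise ConfigurationError(
                f"washout={self.washout} consumes the training portion at "
                f"length {self.length}"
            )


@dataclass
class MCResult:
    """Per-delay squared correlations and their (truncated) sum."""

    per_delay: np.ndarray  # (k_max,), MC_k for k = 1..k_max
    total: float
    k_max: int

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "k_max": self.k_max,
            "per_delay": self.per_delay.tolist(),
        }


def estimate_mc(
    mats: ReservoirMatrices, esn: ESNConfig, mc: MCConfig
) -> MCResult:
    """Estimate memory capacity of a reservoir with a single input unit.

    The reservoir is driven continuously (no per-sample reset) by an
    i.i.d. uniform(−1, 1) sequence of ``mc.length`` steps; one ridge
    readout per delay is fitted on the training portion and the squared
    correlation is computed on the held-out portion.  Delays whose
    reconstruction is constant contribute 0 with a logged warning.
    """
    if mats.w_in.shape[1] != 1:
        raise ConfigurationError(
            f"memory capacity requires a single input channel, got D={mats.w_in.shape[1]}"
        )
    rng = np.random.default_rng(mc.seed)
    u = rng.uniform(-1.0, 1.0, size=mc.length)

    drive_cfg = ESNConfig(
        alpha=esn.alpha,
        rho_target=esn.rho_target,
        ridge_lambda=esn.ridge_lambda,
        washout=0,
        reset_per_sample=False,
        activation=esn.activation,
        input_scale=esn.input_scale,
        seed=esn.seed,
    )
    states = encode_sequence(u[:, None], mats, drive_cfg)  # (N, T), x after u[t]

    start = max(mc.washout, mc.k_max)
    times = np.arange(start, mc.length)
    n_train = int(round(times.shape[0] * mc.train_fraction))
    if n_train < 2 or times.shape[0] - n_train < 2:
        raise ConfigurationError("sequence too short for the requested split")
    t_train, t_test = times[:n_train], times[n_train:]

    x_tr, x_te = states[:, t_train], states[:, t_test]
    # delayed targets: column k-1 holds u(t-k)
    delays = np.arange(1, mc.k_max + 1)
    y_tr = u[t_train[:, None] - delays[None, :]]  # (T_tr, k_max)
    y_te = u[t_test[:, None] - delays[None, :]]

    gram = x_tr @ x_tr.T
    gram[np.diag_indices_from(gram)] += MC_RIDGE_LAMBDA
    w = scipy.linalg.solve(gram, x_tr @ y_tr, assume_a="pos")  # (N, k_max)
    pred = x_te.T @ w  # (T_te, k_max)

    pred_sd = pred.std(axis=0)
    target_sd = y_te.std(axis=0)
    per_delay = np.zeros(mc.k_max)
    valid = (pred_sd > 0) & (target_sd > 0)
    if not valid.all():
        logger.warning(
            "constant reconstruction at %d of %d delays; their MC_k set to 0",
            int((~valid).sum()),
            mc.k_max,
        )
    cov = ((pred - pred.mean(axis=0)) * (y_te - y_te.mean(axis=0))).mean(axis=0)
    per_delay[valid] = (cov[valid] / (pred_sd[valid] * target_sd[valid])) ** 2
    per_delay = np.clip(per_delay, 0.0, 1.0)
    return MCResult(per_delay=per_delay, total=float(per_delay.sum()), k_max=mc.k_max)


def mc_parameter_sweep(
    m_values,
    p1_values,
    p2_values,
    n: int = 600,
    esn: ESNConfig | None = None,
    mc: MCConfig | None = None,
    repeats: int = 3,
    seed: int = 0,
    rho_target: float = 0.85,
    input_scale: float = 0.1,
    max_retries: int = 5,
):
    """Mean memory capacity over a grid of (M, P1, P2) triples.

    For each triple, ``repeats`` independently seeded reservoirs are
    generated and their total MC averaged.  Triples with P2 > P1 are
    skipped (they violate the topology's sparsity ordering).  Degenerate
    realizations (spectral radius 0) are redrawn with a fresh seed up to
    ``max_retries`` times.

    Returns ``(table, best)`` where ``table`` is a tidy DataFrame with
    columns M, P1, P2, mean_mc, sd_mc and ``best`` is the row-maximizing
    (M, P1, P2) triple.
    """
    import pandas as pd

    esn = esn or ESNConfig()
    mc = mc or MCConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for p1 in p1_values:
        for m in m_values:
            for p2 in p2_values:
                if p2 > p1:
                    continue
                totals = []
                for rep in range(repeats):
                    child = np.random.SeedSequence(
                        entropy=ss.entropy, spawn_key=(len(rows), rep)
                    )
                    res_seed, mc_seed = (
                        int(s) % (2**31) for s in child.generate_state(2)
                    )
                    for attempt in range(max_retries):
                        cfg = TopologyConfig(
                            n=n,
                            modules=int(m),
                            p_intra=float(p1),
                            p_inter=float(p2),
                            seed=res_seed + attempt,
                        )
                        try:
                            mats = generate_reservoir(
                                cfg, rho_target, n_inputs=1, input_scale=input_scale
                            )
                            break
                        except DegenerateReservoirError:
                            if attempt == max_retries - 1:
                                raise
                    run_mc = MCConfig(
                        length=mc.length,
                        k_max=mc.k_max,
                        washout=mc.washout,
                        train_fraction=mc.train_fraction,
                        seed=mc_seed,
                    )
                    totals.append(estimate_mc(mats, esn, run_mc).total)
                totals = np.asarray(totals)
                rows.append(
                    {
                        "M": int(m),
                        "P1": float(p1),
                        "P2": float(p2),
                        "mean_mc": float(totals.mean()),
                        "sd_mc": float(totals.std(ddof=0)),
                    }
                )
    if not rows:
        raise ConfigurationError("empty memory-capacity sweep grid")
    table = pd.DataFrame(rows)
    best_row = table.loc[table["mean_mc"].idxmax()]
    best = (int(best_row["M"]), float(best_row["P1"]), float(best_row["P2"]))
    return table, best
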