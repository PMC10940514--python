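"""Degree-distribution heterogeneity of a reservoir.

Modular reservoirs are sparser and less uniform than Erdős–Rényi ones;
the heterogeneity of the resulting in-degree distribution is summarized
by the coefficient of variation (CV = SD / mean).  In-degrees follow
the row convention of the state update ``x ← W_rc x``: row ``i`` of the
recurrent matrix collects the connections *into* neuron ``i``.

Two degree modes are provided: ``binary`` counts nonzero incoming
connections; ``weighted`` takes the signed row sum.  With the package's
sign-symmetric weights the weighted mean is a near-zero random quantity,
so the weighted CV is reported signed together with an instability flag
when the mean is tiny relative to the SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ShapeError, UndefinedStatisticError

__all__ = ["DegreeStats", "in_degree", "degree_stats", "degree_report"]

#: |mean| below this multiple of the SD marks the CV as unstable.
CV_STABILITY_RATIO = 1e-6


@dataclass(frozen=True)
class DegreeStats:
    """Population summary of a degree vector."""

    degrees: np.ndarray
    mean: float
    variance: float
    sd: float
    cv: float
    unstable: bool

    def as_row(self) -> dict:
        return {
            "mean": self.mean,
            "variance": self.variance,
            "sd": self.sd,
            "cv": self.cv,
            "unstable": self.unstable,
        }


def in_degree(w: np.ndarray, mode: str = "weighted") -> np.ndarray:
    """Per-node in-degree of a recurrent matrix.

    ``binary`` counts nonzero entries per row; ``weighted`` sums the
    signed weights per row.
    """
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {w.shape}")
    if mode == "binary":
        return np.count_nonzero(w, axis=1).astype(float)
    if mode == "weighted":
        return w.sum(axis=1)
    raise ConfigurationError(f"unknown degree mode {mode!r}; use 'binary' or 'weighted'")


def degree_stats(degrees: np.ndarray) -> DegreeStats:
    """Population mean/variance/SD and coefficient of variation.

    Uses population statistics (divide by N): the degrees describe the
    whole network, not a sample from a larger one.  The CV is signed
    (sd / mean) and flagged unstable when |mean| < 1e-6 · sd; a mean of
    exactly zero raises :class:`UndefinedStatisticError`.
    """
    degrees = np.asarray(degrees, dtype=float).ravel()
    if degrees.shape[0] < 2:
        raise ConfigurationError(
            f"need at least 2 nodes for degree statistics, got {degrees.shape[0]}"
        )
    mean = float(degrees.mean())
    variance = float(degrees.var(ddof=0))
    sd = float(np.sqrt(variance))
    if mean == 0.0:
        if sd == 0.0:
            # all-zero degrees: no dispersion, CV defined as 0
            return DegreeStats(degrees, mean, variance, sd, 0.0, False)
        raise UndefinedStatisticError(
            "coefficient of variation is undefined at mean 0; inspect the "
            "unstable flag on nearby realizations"
        )
    unstable = abs(mean) < CV_STABILITY_RATIO * sd
    return DegreeStats(degrees, mean, variance, sd, sd / mean, unstable)


def degree_report(w: np.ndarray, modes: tuple[str, ...] = ("binary", "weighted")) -> pd.DataFrame:
    """Summary table of degree statistics per mode for one reservoir."""
    rows = []
    for mode in modes:
        stats = degree_stats(in_degree(w, mode))
        rows.append({"mode": mode, **stats.as_row()})
    return pd.DataFrame(rows)
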