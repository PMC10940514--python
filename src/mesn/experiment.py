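"""Experiment protocol: labels, cross-validation, grid search, metrics.

Binary tasks over the 1–9 affective ratings:

* ``valence`` / ``arousal`` — high iff the rating exceeds 5, low
  otherwise (a rating of exactly 5 is low);
* ``stress_calm`` — stress iff valence <= 3 and arousal >= 5; calm iff
  4 <= valence <= 6 and arousal < 4; every other record is excluded.

The positive class is high valence / high arousal / stress.

Model selection follows a two-phase protocol.  Phase I fixes the
spectral radius (0.85) and leak rate (0.25) and exhaustively searches
the modular-topology grid — P1 over {0.05..0.3}, M over
{1,2,3,4,5,6,8,10}, P2 over {P1/5, 2P1/5, ..., P1} (240 triples) — by
repeated 5-fold cross-validation (3 repeats, a fresh reservoir per
repeat), keeping the first strictly-best triple.  Phase II fixes the
winning topology and tunes the leak rate per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .esn import ESNConfig, encode_sequence, fit_readout, one_hot, predict
from .exceptions import (
    ConfigurationError,
    DegenerateFoldError,
    InvalidSplitError,
    ShapeError,
)
from .topology import TopologyConfig, generate_reservoir

__all__ = [
    "TaskLabeling",
    "MetricReport",
    "GridSpec",
    "EvalResult",
    "GridSearchResult",
    "binarize_labels",
    "kfold_indices",
    "evaluate_config",
    "grid_search",
    "leak_rate_sweep",
    "confusion_metrics",
]

TASKS = ("valence", "arousal", "stress_calm")
#: Marker for records excluded by the stress/calm rule.
EXCLUDED = -1


@dataclass(frozen=True)
class TaskLabeling:
    """Binary labels (1 = positive class) with an inclusion mask."""

    task: str
    labels: np.ndarray  # full-length; EXCLUDED where not labelled
    included: np.ndarray  # boolean mask

    @property
    def kept_labels(self) -> np.ndarray:
        return self.labels[self.included]


def binarize_labels(ratings: pd.DataFrame, task: str) -> TaskLabeling:
    """Apply a task's labelling rule to a ratings table.

    ``ratings`` must contain ``valence`` and ``arousal`` columns on the
    1–9 scale.  Returns per-record binary labels (1 = high / stress,
    0 = low / calm) and the inclusion mask; only ``stress_calm``
    excludes records.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; choose from {TASKS}")
    v = np.asarray(ratings["valence"], dtype=float)
    a = np.asarray(ratings["arousal"], dtype=float)
    for name, arr in (("valence", v), ("arousal", a)):
        if np.any((arr < 1) | (arr > 9)):
            raise ConfigurationError(f"{name} ratings must lie in [1, 9]")
    n = v.shape[0]
    labels = np.full(n, EXCLUDED, dtype=int)
    if task == "valence":
        labels = (v > 5).astype(int)
        included = np.ones(n, dtype=bool)
    elif task == "arousal":
        labels = (a > 5).astype(int)
        included = np.ones(n, dtype=bool)
    else:
        stress = (v <= 3) & (a >= 5)
        calm = (v >= 4) & (v <= 6) & (a < 4)
        labels[stress] = 1
        labels[calm] = 0
        included = stress | calm
    return TaskLabeling(task=task, labels=labels, included=included)


def kfold_indices(n: int, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Random balanced partition into ``folds`` test folds.

    Returns a length-``n`` array of fold ids in {0..folds-1}; fold
    sizes differ by at most one and the partition is deterministic
    given the seed.
    """
    if n < folds:
        raise InvalidSplitError(f"cannot split {n} samples into {folds} folds")
    assignment = np.empty(n, dtype=int)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.empty((n, 1)))):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# Cross-validated evaluation of one topology
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Cross-validation outcome for one (M, P1, P2) configuration."""

    mean_accuracy: float
    per_repeat: np.ndarray  # mean accuracy per repeat
    fold_table: pd.DataFrame  # repeat, fold, accuracy
    seeds: list[int] = field(default_factory=list)


def _cv_one_reservoir(
    states: np.ndarray,
    labels: np.ndarray,
    folds: int,
    fold_seed: int,
    ridge_lambda: float,
) -> np.ndarray:
    """Per-fold accuracies for pre-encoded states (columns = samples)."""
    n = labels.shape[0]
    assignment = kfold_indices(n, folds, fold_seed)
    accs = np.empty(folds)
    for fold in range(folds):
        test = assignment == fold
        train = ~test
        y_train = labels[train]
        if np.unique(y_train).shape[0] < 2:
            raise DegenerateFoldError(
                f"training fold {fold} contains a single class"
            )
        w = fit_readout(states[:, train], one_hot(y_train, 2), ridge_lambda)
        _, pred = predict(w, states[:, test])
        accs[fold] = float(np.mean(pred == labels[test]))
    return accs


def evaluate_config(
    features: np.ndarray,
    labels: np.ndarray,
    topo: TopologyConfig,
    esn: ESNConfig,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> EvalResult:
    """Repeated k-fold accuracy of one reservoir topology.

    Each repeat draws a fresh reservoir realization (new topology seed)
    and a fresh fold partition, encodes all samples once, and fits one
    readout per fold.  Returns the grand mean over repeats and folds
    plus the per-repeat breakdown.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2:
        raise ShapeError(f"features must be (samples, dim), got {features.shape}")
    if features.shape[0] != labels.shape[0]:
        raise ShapeError("features and labels disagree on sample count")
    if features.shape[0] == 0:
        raise ConfigurationError("empty dataset")

    rows = []
    repeat_means = np.empty(repeats)
    seeds_used: list[int] = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(repeats)):
        res_seed, fold_seed = (int(s) % (2**31) for s in child.generate_state(2))
        seeds_used.extend([res_seed, fold_seed])
        cfg = replace(topo, seed=res_seed)
        mats = generate_reservoir(
            cfg, esn.rho_target, n_inputs=features.shape[1], input_scale=esn.input_scale
        )
        states = encode_sequence(features, mats, esn)
        accs = _cv_one_reservoir(states, labels, folds, fold_seed, esn.ridge_lambda)
        repeat_means[rep] = accs.mean()
        rows.extend(
            {"repeat": rep, "fold": f, "accuracy": acc} for f, acc in enumerate(accs)
        )
    return EvalResult(
        mean_accuracy=float(repeat_means.mean()),
        per_repeat=repeat_means,
        fold_table=pd.DataFrame(rows),
        seeds=seeds_used,
    )


# ---------------------------------------------------------------------------
# Phase I grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """The Phase-I topology grid.

    P2 is derived from each P1 as the five fractions
    {1/5, 2/5, 3/5, 4/5, 1} of P1, so P2 never exceeds P1.  The default
    grid evaluates 6 × 8 × 5 = 240 triples.
    """

    p1_values: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    m_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10)
    p2_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    cv_folds: int = 5
    cv_repeats: int = 3

    def __post_init__(self) -> None:
        if not (self.p1_values and self.m_values and self.p2_fractions):
            raise ConfigurationError("grid axes must be non-empty")
        if any(f <= 0 or f > 1 for f in self.p2_fractions):
            raise ConfigurationError("P2 fractions must lie in (0, 1]")

    def triples(self):
        """Yield (P1, M, P2) in the canonical loop order."""
        for p1 in self.p1_values:
            for m in self.m_values:
                for frac in self.p2_fractions:
                    yield p1, m, p1 * frac

    @property
    def n_triples(self) -> int:
        return len(self.p1_values) * len(self.m_values) * len(self.p2_fractions)


@dataclass
class GridSearchResult:
    best_m: int
    best_p1: float
    best_p2: float
    best_accuracy: float
    table: pd.DataFrame


def grid_search(
    features: np.ndarray | None,
    labels: np.ndarray | None,
    grid: GridSpec,
    esn: ESNConfig | None = None,
    n: int = 600,
    seed: int = 0,
    evaluator=None,
) -> GridSearchResult:
    """Exhaustive Phase-I search over the (P1, M, P2) grid.

    Every triple is scored by :func:`evaluate_config` (repeated k-fold
    mean accuracy); the argmax is kept under a strict-improvement rule,
    so ties resolve to the first triple encountered in loop order.

    ``evaluator`` may replace the cross-validated scoring with any
    callable ``(m, p1, p2) -> accuracy`` — used for fast protocol tests
    and for plugging in alternative criteria (e.g. memory capacity).
    """
    esn = esn or ESNConfig()
    rows = []
    best = None  # (acc, m, p1, p2)
    ss = np.random.SeedSequence(seed)
    for idx, (p1, m, p2) in enumerate(grid.triples()):
        if evaluator is not None:
            acc = float(evaluator(m, p1, p2))
            sd = 0.0
        else:
            triple_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(idx,)
                ).generate_state(1)[0]
            ) % (2**31)
            topo = TopologyConfig(n=n, modules=m, p_intra=p1, p_inter=p2, seed=0)
            result = evaluate_config(
                features,
                labels,
                topo,
                esn,
                folds=grid.cv_folds,
                repeats=grid.cv_repeats,
                seed=triple_seed,
            )
            acc = result.mean_accuracy
            sd = float(result.per_repeat.std(ddof=0))
        rows.append({"P1": p1, "M": m, "P2": p2, "mean_acc": acc, "sd_acc": sd})
        if best is None or acc > best[0]:
            best = (acc, m, p1, p2)
    table = pd.DataFrame(rows)
    return GridSearchResult(
        best_m=int(best[1]),
        best_p1=float(best[2]),
        best_p2=float(best[3]),
        best_accuracy=float(best[0]),
        table=table,
    )


def leak_rate_sweep(
    features: np.ndarray,
    labels: np.ndarray,
    topo: TopologyConfig,
    esn: ESNConfig,
    alphas: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5),
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Phase II: tune the leak rate on a fixed topology.

    Returns the best alpha (strict improvement, first found) and the
    full alpha → accuracy table.
    """
    rows = []
    best = None
    for alpha in alphas:
        cfg = replace(esn, alpha=alpha)
        result = evaluate_config(
            features, labels, topo, cfg, folds=folds, repeats=repeats, seed=seed
        )
        rows.append({"alpha": alpha, "mean_acc": result.mean_accuracy})
        if best is None or result.mean_accuracy > best[0]:
            best = (result.mean_accuracy, alpha)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricReport:
    """Binary classification metrics derived from a 2×2 confusion table.

    ``confusion`` is laid out ``[[TN, FP], [FN, TP]]`` with class 1
    (high / stress) as the positive class.  Ratios with a zero
    denominator are NaN and named in ``undefined``.
    """

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    confusion: np.ndarray
    undefined: tuple[str, ...] = ()


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """Precision, sensitivity, specificity, accuracy and F1 from labels."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape[0] != y_pred.shape[0]:
        raise ShapeError("label sequences differ in length")
    if y_true.shape[0] == 0:
        raise ConfigurationError("cannot compute metrics on empty labels")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = (tp + tn) / y_true.shape[0]
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricReport(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        f1=f1,
        confusion=np.array([[tn, fp], [fn, tp]]),
        undefined=tuple(undefined),
    )
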