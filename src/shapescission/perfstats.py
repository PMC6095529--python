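"""Performance statistics for confusion matrices.

The central statistic is the inverse mean absolute distance between a
response matrix R and a prediction matrix P, both on the [0, 1] scale::

    perf = 1 - mean(|R - P|)

where the perfect prediction matrix is the identity (all zeros but a
diagonal of ones).  perf = 1 means errorless categorization; comparing a
*binary* response matrix against i.i.d. uniform[0, 1] random prediction
matrices gives perf = 0.5 in expectation (E|b - u| = 1/2 for b in {0, 1},
u ~ U(0, 1)), which serves as the chance level.

Alongside perf we report the squared Pearson correlation (R²) between
the flattened response matrix and the prediction, a percentile bootstrap
95% CI over observers, a random-prediction-matrix null ensemble, and the
mean pairwise correlation between individual observers' matrices
(inter-observer consistency).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .confusion import ConfusionMatrix


def _as_unit(matrix) -> np.ndarray:
    if isinstance(matrix, ConfusionMatrix):
        return matrix.unit_values
    return np.asarray(matrix, dtype=float)


def identity_prediction(n: int) -> np.ndarray:
    """The perfect prediction matrix: all zeros but a diagonal of ones."""
    return np.eye(n)


def perf_score(response, prediction) -> float:
    """``1 - mean(|response - prediction|)`` over all cells.

    Both matrices must share a shape and live on [0, 1] (percent
    matrices are converted automatically).
    """
    r, p = _as_unit(response), _as_unit(prediction)
    if r.shape != p.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {p.shape}")
    return float(1.0 - np.abs(r - p).mean())


def r2_to_prediction(response, prediction=None) -> float:
    """Squared Pearson correlation of the flattened matrices.

    ``prediction`` defaults to the identity matrix.
    """
    r = _as_unit(response)
    p = identity_prediction(r.shape[0]) if prediction is None else _as_unit(prediction)
    if r.shape != p.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {p.shape}")
    rf, pf = r.ravel(), p.ravel()
    if np.ptp(rf) == 0 or np.ptp(pf) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    rho = np.corrcoef(rf, pf)[0, 1]
    return float(rho ** 2)


def bootstrap_ci(individual_matrices: list, prediction=None, n_boot: int = 10_000,
                 seed: int | None = None, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of perf, resampling observers.

    Each replicate resamples observers with replacement, averages their
    matrices, and scores perf against ``prediction`` (identity by
    default).
    """
    if len(individual_matrices) < 2:
        raise ValueError("bootstrap over observers needs at least 2 observers")
    mats = np.stack([_as_unit(m) for m in individual_matrices])
    pred = identity_prediction(mats.shape[1]) if prediction is None else _as_unit(prediction)
    rng = np.random.default_rng(seed)
    n = mats.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    # vectorized: mean over resampled observers, then perf per replicate
    perf_samples = 1.0 - np.abs(mats[idx].mean(axis=1) - pred).mean(axis=(1, 2))
    lo, hi = np.quantile(perf_samples, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def null_perf(individual_matrices: list, n_null: int = 100_000,
              seed: int | None = None, null_kind: str = "uniform") -> dict:
    """Null ensemble of perf against random prediction matrices.

    ``uniform`` draws prediction matrices with i.i.d. uniform[0, 1]
    entries; ``permutation`` uses row-permuted identity matrices.  Each
    draw is scored against the group-mean response matrix.  Returns the
    null mean, a percentile 95% interval, and the mean R² against the
    random predictions.
    """
    if n_null < 1:
        raise ValueError("n_null must be at least 1")
    mats = np.stack([_as_unit(m) for m in individual_matrices])
    group = mats.mean(axis=0)
    n_rows, n_cols = group.shape
    rng = np.random.default_rng(seed)

    if null_kind == "uniform":
        preds = rng.uniform(size=(n_null, n_rows, n_cols))
    elif null_kind == "permutation":
        if n_rows != n_cols:
            raise ValueError("permutation null requires a square matrix")
        eye = np.eye(n_rows)
        perms = np.argsort(rng.uniform(size=(n_null, n_rows)), axis=1)
        preds = eye[perms]
    else:
        raise ValueError(f"unknown null_kind {null_kind!r}")

    perfs = 1.0 - np.abs(group[None] - preds).mean(axis=(1, 2))
    gf = group.ravel()
    pf = preds.reshape(n_null, -1)
    # mean R^2 vs random predictions; constant draws (impossible for
    # uniform, possible in principle) would be excluded
    gc = gf - gf.mean()
    pc = pf - pf.mean(axis=1, keepdims=True)
    denom = np.sqrt((gc ** 2).sum() * (pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        r = (pc @ gc) / denom
    r2 = np.nanmean(r ** 2)
    lo, hi = np.quantile(perfs, [0.025, 0.975])
    return {
        "null_perf_mean": float(perfs.mean()),
        "null_ci_low": float(lo),
        "null_ci_high": float(hi),
        "null_r2_mean": float(r2),
        "n_null": int(n_null),
        "null_kind": null_kind,
    }


@dataclass(frozen=True)
class PerformanceSummary:
    perf: float
    r2: float
    ci_low: float
    ci_high: float
    null_perf_mean: float
    null_ci_low: float
    null_ci_high: float
    null_r2_mean: float
    n_boot: int
    n_null: int
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def performance_summary(individual_matrices: list, prediction=None,
                        n_boot: int = 10_000, n_null: int = 100_000,
                        seed: int | None = None,
                        null_kind: str = "uniform") -> PerformanceSummary:
    """perf, R², bootstrap CI and null ensemble for one matrix set."""
    mats = [_as_unit(m) for m in individual_matrices]
    group = np.mean(mats, axis=0)
    pred = identity_prediction(group.shape[0]) if prediction is None else _as_unit(prediction)
    rng = np.random.default_rng(seed)
    ci = bootstrap_ci(mats, pred, n_boot=n_boot, seed=int(rng.integers(2**31)))
    null = null_perf(mats, n_null=n_null, seed=int(rng.integers(2**31)),
                     null_kind=null_kind)
    return PerformanceSummary(
        perf=perf_score(group, pred),
        r2=r2_to_prediction(group, pred),
        ci_low=ci[0], ci_high=ci[1],
        null_perf_mean=null["null_perf_mean"],
        null_ci_low=null["null_ci_low"], null_ci_high=null["null_ci_high"],
        null_r2_mean=null["null_r2_mean"],
        n_boot=n_boot, n_null=n_null, seed=seed,
    )


@dataclass(frozen=True)
class ConsistencySummary:
    mean_r: float
    n_pairs: int
    grouping: str

    def to_dict(self) -> dict:
        return asdict(self)


def observer_consistency(individual_matrices: list,
                         grouping: str = "per observer") -> ConsistencySummary:
    """Mean Pearson correlation over all unordered observer pairs.

    Observers with constant matrices (undefined correlation) are
    excluded with a warning.
    """
    mats = []
    for i, m in enumerate(individual_matrices):
        flat = _as_unit(m).ravel()
        if np.ptp(flat) == 0:
            warnings.warn(f"observer {i} has a constant matrix; excluded "
                          "from consistency")
            continue
        mats.append(flat)
    if len(mats) < 2:
        raise ValueError("consistency needs at least 2 non-constant observers")
    rs = [np.corrcoef(a, b)[0, 1] for a, b in itertools.combinations(mats, 2)]
    return ConsistencySummary(float(np.mean(rs)), len(rs), grouping)
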