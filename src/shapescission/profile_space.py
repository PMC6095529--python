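"""PCA of rating profiles and the material/transformation scission analysis.

Every stimulus group in a rating task has a *profile*: its mean rating on
each scale.  Plotting the profiles in the space of the first principal
components shows whether responses are organized by material, by
transformation, or both — on real data the material-rating profiles
cluster by material and not by transformation, and vice versa, i.e.
observers separate the intrinsic (material) from the extrinsic
(transformation) cause of the observed shape.

A silhouette-style separability score in the first ``k`` components makes
the visual claim quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .design import ExperimentDesign, Task

_TRUE_COL = {"material": "true_material", "transformation": "true_transformation"}


@dataclass(frozen=True)
class ProfileMatrix:
    """Aggregated rating profiles: rows = stimulus groups, columns = scales."""

    row_material: tuple[str, ...]
    row_transformation: tuple[str, ...]
    scales: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_material), len(self.scales)):
            raise ValueError("profile shape does not match labels")
        if len(self.row_material) != len(self.row_transformation):
            raise ValueError("row label vectors must align")
        if np.isnan(v).any():
            raise ValueError("profiles contain missing entries")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("profile values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def labels(self, factor: str) -> tuple[str, ...]:
        return self.row_material if factor == "material" else self.row_transformation

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.scales))
        df.insert(0, "material", self.row_material)
        df.insert(1, "transformation", self.row_transformation)
        return df


def build_profiles(trials: pd.DataFrame, design: ExperimentDesign,
                   aggregate_by: tuple[str, ...] = ("material", "transformation"),
                   ) -> ProfileMatrix:
    """Mean rating per aggregate group x scale.

    The default aggregation gives one row per material x transformation
    cell (24 rows x n_scales columns); passing a single factor aggregates
    down to its levels.
    """
    if (trials["task"] != Task.RATING.value).any():
        raise ValueError("build_profiles expects a rating-task table")
    group_cols = [_TRUE_COL[f] for f in aggregate_by]
    grouped = (
        trials.groupby(group_cols + ["block_scale"])["response_value"].mean().unstack("block_scale")
    )
    if grouped.isna().any().any():
        raise ValueError("empty aggregate cell in profile construction")
    scales = tuple(design.rating_scales)
    grouped = grouped[list(scales)]

    idx = grouped.index
    if len(group_cols) == 1:
        only = aggregate_by[0]
        labels = tuple(idx)
        mats = labels if only == "material" else ("",) * len(labels)
        trans = labels if only == "transformation" else ("",) * len(labels)
    else:
        frame = idx.to_frame(index=False)
        mats = tuple(frame[_TRUE_COL["material"]])
        trans = tuple(frame[_TRUE_COL["transformation"]])
    return ProfileMatrix(mats, trans, scales, grouped.to_numpy())


@dataclass(frozen=True)
class ProfileEmbedding:
    """Principal-component embedding of a profile matrix."""

    loadings: np.ndarray          # (n_scales, n_components)
    scores: np.ndarray            # (n_rows, n_components)
    explained_variance_ratio: np.ndarray
    row_material: tuple[str, ...]
    row_transformation: tuple[str, ...]

    def labels(self, factor: str) -> tuple[str, ...]:
        return self.row_material if factor == "material" else self.row_transformation


def pca_profiles(profiles: ProfileMatrix, n_components: int | None = None) -> ProfileEmbedding:
    """Column-mean-centered PCA via eigendecomposition of the covariance.

    Columns are centered but not scaled (all share the [0, 1] rating
    unit).  Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive.
    """
    x = profiles.values
    n_rows, n_cols = x.shape
    if n_rows < 2:
        raise ValueError("PCA needs at least 2 profile rows")
    max_comp = min(n_rows - 1, n_cols)
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)

    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / (n_rows - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive
    for c in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, c]))
        if evecs[pivot, c] < 0:
            evecs[:, c] *= -1

    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    loadings = evecs[:, :n_components]
    scores = xc @ loadings
    return ProfileEmbedding(loadings, scores, ratio[:n_components],
                            profiles.row_material, profiles.row_transformation)


def label_separability(embedding: ProfileEmbedding, labels, k: int = 3) -> float:
    """Mean silhouette of embedded rows under a labeling, in [-1, 1].

    Uses the first ``k`` components.  All-identical points (degenerate
    distances) score 0 by convention; a single distinct label is an
    error.
    """
    labels = list(labels)
    uniq = set(labels)
    if len(uniq) < 2:
        raise ValueError("separability needs at least 2 distinct labels")
    pts = embedding.scores[:, : min(k, embedding.scores.shape[1])]
    if np.allclose(pts, pts[0]):
        return 0.0
    if any(labels.count(u) < 1 for u in uniq):  # pragma: no cover - by construction
        raise ValueError("every label needs at least one row")
    return float(silhouette_score(pts, labels))
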