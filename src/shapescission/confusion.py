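"""Confusion matrices from naming, rating and forced-choice trial tables.

Three semantics are supported, matching the three tasks:

``percent_of_responses``
    Naming: entry (i, j) is the percentage of *all* responses for actual
    category i that named category j.  Responses outside the design's
    label sets (the OTHER bucket) enter the denominator but not the
    square matrix, so rows need not sum to 100; their mass is reported
    per row in ``other_mass``.
``mean_rating``
    Rating: entry (i, j) is the mean [0, 1] rating on scale j for stimuli
    of actual category i.
``choice_proportion``
    Forced choice: entry (i, j) is the proportion of stimuli of actual
    category i labeled j; rows sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign, Task
from .trials import OTHER

_TRUE_COL = {"material": "true_material", "transformation": "true_transformation"}


class EmptyCellError(ValueError):
    """An actual-category cell has no responses; balanced designs make
    this a data problem, never a value."""


@dataclass(frozen=True)
class ConfusionMatrix:
    actual_labels: tuple[str, ...]
    response_labels: tuple[str, ...]
    values: np.ndarray
    semantics: str  # percent_of_responses | mean_rating | choice_proportion
    other_mass: np.ndarray | None = None  # per-row OTHER percentage (naming)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.actual_labels), len(self.response_labels)):
            raise ValueError("matrix shape does not match labels")
        object.__setattr__(self, "values", v)
        if self.semantics == "choice_proportion":
            if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("choice proportions must sum to 1 per row")
        elif self.semantics == "mean_rating":
            if (v < -1e-12).any() or (v > 1 + 1e-12).any():
                raise ValueError("mean ratings must lie in [0, 1]")
        elif self.semantics == "percent_of_responses":
            om = np.zeros(len(self.actual_labels)) if self.other_mass is None \
                else np.asarray(self.other_mass, dtype=float)
            object.__setattr__(self, "other_mass", om)
            if not np.allclose(v.sum(axis=1) + om, 100.0, atol=1e-9):
                raise ValueError("row sum + OTHER mass must equal 100")
        else:
            raise ValueError(f"unknown semantics {self.semantics!r}")

    @property
    def unit_values(self) -> np.ndarray:
        """Values on the [0, 1] scale (percent matrices divided by 100)."""
        if self.semantics == "percent_of_responses":
            return self.values / 100.0
        return self.values

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.actual_labels),
                          columns=list(self.response_labels))
        df.index.name = "actual"
        if self.semantics == "percent_of_responses":
            df[OTHER] = self.other_mass
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def naming_confusion(coded: pd.DataFrame, design: ExperimentDesign,
                     factor: str) -> ConfusionMatrix:
    """Percent-of-responses confusion matrix from a coded naming table.

    ``factor`` selects the question ('material' or 'transformation');
    rows are the actual categories, columns the canonical responses.
    OTHER-coded responses — and responses naming a category of the other
    factor — count in denominators only, so rows need not reach 100.
    """
    if "coded_category" not in coded.columns:
        raise ValueError("naming_confusion requires a coded table "
                         "(run code_naming_responses first)")
    sub = coded[coded["block_scale"] == factor]
    if sub.empty:
        raise EmptyCellError(f"no coded responses for factor {factor!r}")
    true_col = _TRUE_COL[factor]
    present = set(sub[true_col])
    # rows: design-ordered actual categories with at least one response
    # (a category in the table but without responses would be undefined)
    actual = tuple(a for a in design.labels(factor) if a in present)
    if not actual:
        raise EmptyCellError(f"no actual categories with responses for {factor!r}")
    responses = design.labels(factor)
    values = np.zeros((len(actual), len(responses)))
    other = np.zeros(len(actual))
    for i, a in enumerate(actual):
        rows = sub[sub[true_col] == a]
        n = len(rows)
        counts = rows["coded_category"].value_counts()
        for j, r in enumerate(responses):
            values[i, j] = 100.0 * counts.get(r, 0) / n
        accounted = values[i].sum()
        other[i] = 100.0 - accounted
    return ConfusionMatrix(actual, responses, values, "percent_of_responses", other)


def _per_observer(trials: pd.DataFrame, build) -> ConfusionMatrix:
    mats = [build(g) for _, g in trials.groupby("observer_id", sort=True)]
    ref = mats[0]
    stacked = np.stack([m.values for m in mats])
    return ConfusionMatrix(ref.actual_labels, ref.response_labels,
                           stacked.mean(axis=0), ref.semantics)


def rating_confusion(trials: pd.DataFrame, design: ExperimentDesign,
                     average: str = "group") -> ConfusionMatrix:
    """Mean-rating matrix: actual category x rating scale.

    Ratings are averaged over exemplars and repetitions; ``average``
    chooses between pooling all trials ('group') and averaging
    per-observer matrices ('per_observer') — identical under a balanced
    design.
    """
    if (trials["task"] != Task.RATING.value).any():
        raise ValueError("rating_confusion expects a rating-task table")
    factor = design.rating_factor
    true_col = _TRUE_COL[factor]
    actual = design.labels(factor)
    scales = tuple(design.rating_scales)

    def build(tab: pd.DataFrame) -> ConfusionMatrix:
        values = np.empty((len(actual), len(scales)))
        grouped = tab.groupby([true_col, "block_scale"])["response_value"].mean()
        for i, a in enumerate(actual):
            for j, s in enumerate(scales):
                try:
                    values[i, j] = grouped.loc[(a, s)]
                except KeyError:
                    raise EmptyCellError(f"no ratings for actual={a!r} scale={s!r}")
        return ConfusionMatrix(actual, scales, values, "mean_rating")

    if average == "per_observer":
        return _per_observer(trials, build)
    return build(trials)


def afc_confusion(trials: pd.DataFrame, design: ExperimentDesign,
                  average: str = "group") -> ConfusionMatrix:
    """Choice-proportion matrix: actual transformation x chosen transformation."""
    if (trials["task"] != Task.AFC.value).any():
        raise ValueError("afc_confusion expects a forced-choice table")
    actual = tuple(design.transformations)

    def build(tab: pd.DataFrame) -> ConfusionMatrix:
        values = np.zeros((len(actual), len(actual)))
        for i, a in enumerate(actual):
            rows = tab[tab["true_transformation"] == a]
            if rows.empty:
                raise EmptyCellError(f"no choices for actual category {a!r}")
            counts = rows["response_choice"].value_counts()
            for j, r in enumerate(actual):
                values[i, j] = counts.get(r, 0) / len(rows)
        return ConfusionMatrix(actual, actual, values, "choice_proportion")

    if average == "per_observer":
        return _per_observer(trials, build)
    return build(trials)


def per_observer_matrices(trials: pd.DataFrame, design: ExperimentDesign) -> dict[str, ConfusionMatrix]:
    """One confusion matrix per observer (rating or afc tables)."""
    task = trials["task"].iloc[0]
    out = {}
    for obs, tab in trials.groupby("observer_id", sort=True):
        if task == Task.RATING.value:
            out[obs] = rating_confusion(tab, design)
        elif task == Task.AFC.value:
            out[obs] = afc_confusion(tab, design)
        else:
            raise ValueError("per-observer matrices need a coded naming path; "
                             "use naming_confusion on per-observer subsets")
    return out


def subgroup_matrices(trials: pd.DataFrame, design: ExperimentDesign,
                      by: str) -> dict[str, ConfusionMatrix]:
    """One confusion matrix per level of ``by`` ('material'|'transformation').

    Under balance, recombining the subgroup matrices weighted by their
    trial counts reproduces the pooled matrix.
    """
    col = _TRUE_COL[by]
    task = trials["task"].iloc[0]
    out = {}
    for level in design.labels(by):
        sub = trials[trials[col] == level]
        if sub.empty:
            raise EmptyCellError(f"no trials for {by}={level!r}")
        if task == Task.RATING.value:
            out[level] = rating_confusion(sub, design)
        elif task == Task.AFC.value:
            out[level] = afc_confusion(sub, design)
        else:
            out[level] = naming_confusion(
                sub, design, "transformation" if by == "material" else "material")
    return out
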