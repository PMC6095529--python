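"""Experiment designs for causal-history categorization studies.

The studies this package analyses photograph real objects made from a set
of materials, each deformed by one of a set of shape-altering
transformations (its *causal history*), with many executions/viewpoints
per material x transformation cell.  Three task types probe what
observers can recover from the photographs:

* ``naming``  — free naming of the material and of the transformation;
* ``rating``  — a [0, 1] "not true" .. "true" rating of each stimulus on
  one category scale per block (one block per material, or per
  transformation);
* ``afc``     — forced choice among the transformation labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class Task(str, Enum):
    NAMING = "naming"
    RATING = "rating"
    AFC = "afc"


#: default category labels of the reference study
MATERIALS = ("wax", "aluminum foil", "gold foil", "wire", "putty", "cardboard")
TRANSFORMATIONS = ("twisted", "crumpled", "bent", "folded")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of one task.

    Parameters
    ----------
    materials, transformations
        Ordered category labels; together with ``n_exemplars`` they define
        the stimulus set (``len(materials) * len(transformations) *
        n_exemplars`` photographs).
    n_exemplars
        Executions/viewpoints per material x transformation cell.  These
        are replications, not an experimental factor.
    n_observers
        Number of participants.
    task
        One of :class:`Task`.
    rating_scales
        Block labels for the rating task; must equal ``materials`` or
        ``transformations``.  Empty for other tasks.
    stimuli_per_observer
        Stimuli shown to each participant (a subset of the full set for
        naming and rating).
    repetitions
        Blocks per stimulus: 1 for naming/afc, the number of rating
        scales for the rating task (each stimulus is judged once on every
        scale).
    """

    materials: tuple[str, ...]
    transformations: tuple[str, ...]
    n_exemplars: int
    n_observers: int
    task: Task
    rating_scales: tuple[str, ...] = ()
    stimuli_per_observer: int = 0
    repetitions: int = 1

    def __post_init__(self) -> None:
        if len(set(self.materials)) != len(self.materials):
            raise ValueError("duplicate material labels")
        if len(set(self.transformations)) != len(self.transformations):
            raise ValueError("duplicate transformation labels")
        if self.task == Task.RATING:
            scales = tuple(self.rating_scales)
            if scales not in (tuple(self.materials), tuple(self.transformations)):
                raise ValueError(
                    "rating_scales must equal the material or the "
                    "transformation labels"
                )
        elif self.rating_scales:
            raise ValueError(f"rating_scales only apply to the rating task, not {self.task.value}")

    @property
    def n_stimuli(self) -> int:
        return len(self.materials) * len(self.transformations) * self.n_exemplars

    @property
    def rating_factor(self) -> str:
        """Which factor the rating scales address ('material'|'transformation')."""
        if self.task != Task.RATING:
            raise ValueError("rating_factor is defined for rating designs only")
        return "material" if tuple(self.rating_scales) == tuple(self.materials) else "transformation"

    def labels(self, factor: str) -> tuple[str, ...]:
        if factor == "material":
            return tuple(self.materials)
        if factor == "transformation":
            return tuple(self.transformations)
        raise ValueError(f"unknown factor {factor!r}")


def _base(task: Task, **kw) -> dict:
    return dict(
        materials=MATERIALS,
        transformations=TRANSFORMATIONS,
        n_exemplars=30,
        n_observers=15,
        task=task,
        **kw,
    )


def naming_design(n_observers: int = 15, n_exemplars: int = 30) -> ExperimentDesign:
    """Free-naming task: 24 stimuli per observer, one per design cell."""
    d = _base(Task.NAMING)
    d.update(n_observers=n_observers, n_exemplars=n_exemplars,
             stimuli_per_observer=len(MATERIALS) * len(TRANSFORMATIONS))
    return ExperimentDesign(**d)


def rating_design(factor: str = "material", n_observers: int = 15,
                  n_exemplars_used: int = 7) -> ExperimentDesign:
    """Rating task: 168 stimuli per observer (7 exemplars per cell), one
    block per rating scale."""
    scales = MATERIALS if factor == "material" else TRANSFORMATIONS
    d = _base(Task.RATING)
    d.update(
        n_observers=n_observers,
        rating_scales=tuple(scales),
        stimuli_per_observer=len(MATERIALS) * len(TRANSFORMATIONS) * n_exemplars_used,
        repetitions=len(scales),
    )
    return ExperimentDesign(**d)


def afc_design(n_observers: int = 15, n_exemplars: int = 30) -> ExperimentDesign:
    """Forced choice among transformation labels; all stimuli per observer."""
    d = _base(Task.AFC)
    d.update(n_observers=n_observers, n_exemplars=n_exemplars,
             stimuli_per_observer=len(MATERIALS) * len(TRANSFORMATIONS) * n_exemplars)
    return ExperimentDesign(**d)
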