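"""Generative observer models for all three task types.

Real observers judging photographs of transformed objects confuse some
categories more than others — in particular, bent and folded objects are
mixed up, and more so for some materials (e.g. wire mesh) than others.
The simulator captures this with per-cell *confusion kernels*: for every
(true material, true transformation) stimulus cell, a probability vector
over the response categories of the task.  On top of the kernels sit a
lapse rate (uniform random responses), out-of-lexicon naming responses,
additive rating noise, and optional per-observer kernel jitter.

No claim is made that these parameters are estimated from data: they are
free knobs that produce trial tables with *known* confusion structure, so
that every downstream statistic can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign, Task
from .trials import SCHEMA, Lexicon

#: out-of-lexicon strings a naming simulator may emit (responses outside
#: the design's category sets, in the spirit of real free-naming data)
OOV_VOCABULARY = (
    "kinked", "squeezed together", "plastic", "paper", "metal",
    "pressed", "rolled", "chewing gum",
)


@dataclass(frozen=True)
class Kernels:
    """Confusion kernels for one response factor.

    ``probs[i, j, :]`` is the response distribution for stimuli of
    material ``i`` and transformation ``j``; its length matches
    ``response_labels`` (the material labels for material tasks, the
    transformation labels for transformation tasks).
    """

    probs: np.ndarray  # (n_materials, n_transformations, n_responses)
    materials: tuple[str, ...]
    transformations: tuple[str, ...]
    response_labels: tuple[str, ...]
    response_factor: str  # 'material' | 'transformation'

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.materials), len(self.transformations),
                       len(self.response_labels)):
            raise ValueError("kernel array shape does not match labels")
        if (p < 0).any():
            raise ValueError("kernel probabilities must be non-negative")
        if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError("kernel rows must sum to 1")
        object.__setattr__(self, "probs", p)

    def row(self, material: str, transformation: str) -> np.ndarray:
        i = self.materials.index(material)
        j = self.transformations.index(transformation)
        return self.probs[i, j]

    def true_index(self, material: str, transformation: str) -> int:
        true = material if self.response_factor == "material" else transformation
        return self.response_labels.index(true)


def make_default_kernels(
    design: ExperimentDesign,
    response_factor: str = "transformation",
    accuracy: float = 0.8,
    confusability: float = 0.0,
    material_modulation: dict[str, float] | None = None,
    confusable_pair: tuple[str, str] | None = None,
) -> Kernels:
    """Construct kernels with a target accuracy and an elevated confusion
    between one pair of categories.

    Each row starts as ``accuracy`` on the true category and the rest
    spread uniformly.  For the ``confusable_pair`` (default bent/folded
    when responding about transformations) the off-diagonal entry between
    the two pair members becomes ``(base + confusability) * multiplier``
    where ``multiplier`` is the material's entry in
    ``material_modulation`` (default 1), after which the row is
    renormalized.  ``accuracy = 1/k`` with zero confusability gives
    uniform (chance) rows; ``accuracy = 1`` gives identity kernels.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if confusability < 0:
        raise ValueError("confusability must be non-negative")
    mods = dict(material_modulation or {})
    if any(v < 0 for v in mods.values()):
        raise ValueError("material modulation multipliers must be non-negative")

    labels = design.labels(response_factor)
    k = len(labels)
    base_off = (1.0 - accuracy) / (k - 1)

    if confusable_pair is None and response_factor == "transformation" \
            and {"bent", "folded"} <= set(labels):
        confusable_pair = ("bent", "folded")
    pair_idx = None
    if confusable_pair is not None:
        pair_idx = (labels.index(confusable_pair[0]), labels.index(confusable_pair[1]))

    probs = np.zeros((len(design.materials), len(design.transformations), k))
    for i, mat in enumerate(design.materials):
        mult = mods.get(mat, 1.0)
        for j, trans in enumerate(design.transformations):
            true = labels.index(mat if response_factor == "material" else trans)
            row = np.full(k, base_off)
            row[true] = accuracy
            if pair_idx is not None and true in pair_idx:
                other = pair_idx[1] if true == pair_idx[0] else pair_idx[0]
                row[other] = (base_off + confusability) * mult
            s = row.sum()
            if s <= 0:
                raise ValueError("degenerate kernel row (zero total mass)")
            probs[i, j] = row / s
    return Kernels(probs, tuple(design.materials), tuple(design.transformations),
                   tuple(labels), response_factor)


@dataclass(frozen=True)
class ObserverModel:
    """One simulated observer: kernels per response factor plus noise.

    ``lapse_rate`` is the probability of a uniform random response,
    ``oov_rate`` (naming only) of an out-of-lexicon string, and
    ``rating_noise_sd`` the SD of additive Gaussian noise on ratings
    (clipped to [0, 1]).
    """

    observer_id: str
    kernels: dict[str, Kernels]
    lapse_rate: float = 0.0
    oov_rate: float = 0.0
    rating_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for v, name in ((self.lapse_rate, "lapse_rate"), (self.oov_rate, "oov_rate")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be non-negative")


def _jitter_kernels(kernels: Kernels, sd: float, rng: np.random.Generator) -> Kernels:
    """Perturb kernel rows in log space and renormalize.

    Log-space jitter keeps rows valid probability vectors; zero entries
    stay (numerically) zero.
    """
    if sd == 0:
        return kernels
    logp = np.log(np.clip(kernels.probs, 1e-12, None))
    logp = logp + rng.normal(0.0, sd, size=logp.shape)
    p = np.exp(logp - logp.max(axis=-1, keepdims=True))
    p /= p.sum(axis=-1, keepdims=True)
    return replace(kernels, probs=p)


def make_observers(
    kernel_sets: Kernels | list[Kernels],
    n_observers: int,
    lapse_rate: float = 0.0,
    oov_rate: float = 0.0,
    rating_noise_sd: float = 0.0,
    observer_jitter_sd: float = 0.0,
    seed: int | None = None,
) -> list[ObserverModel]:
    """Build a population of observers around shared base kernels."""
    if isinstance(kernel_sets, Kernels):
        kernel_sets = [kernel_sets]
    rng = np.random.default_rng(seed)
    observers = []
    for i in range(n_observers):
        kdict = {
            ks.response_factor: _jitter_kernels(ks, observer_jitter_sd, rng)
            for ks in kernel_sets
        }
        observers.append(
            ObserverModel(f"obs{i:02d}", kdict, lapse_rate, oov_rate, rating_noise_sd)
        )
    return observers


def _empty_row(obs: str, task: str, mat: str, trans: str, ex: int) -> dict:
    return {
        "observer_id": obs, "task": task, "true_material": mat,
        "true_transformation": trans, "exemplar_id": ex, "block_scale": "",
        "response_text": "", "response_value": np.nan, "response_choice": "",
    }


def simulate_afc(design: ExperimentDesign, observers: list[ObserverModel],
                 seed: int | None = None) -> pd.DataFrame:
    """Forced choice: one transformation choice per observer x stimulus.

    Choices are drawn from ``(1 - lapse) * kernel + lapse * uniform``;
    fully reproducible from the seed.
    """
    if design.task != Task.AFC:
        raise ValueError("simulate_afc requires an afc design")
    rng = np.random.default_rng(seed)
    labels = np.array(design.transformations)
    k = len(labels)
    rows = []
    for obs in observers:
        kern = obs.kernels["transformation"]
        for mat in design.materials:
            for trans in design.transformations:
                p = (1 - obs.lapse_rate) * kern.row(mat, trans) + obs.lapse_rate / k
                choices = rng.choice(k, size=design.n_exemplars, p=p)
                for ex in range(design.n_exemplars):
                    row = _empty_row(obs.observer_id, Task.AFC.value, mat, trans, ex)
                    row["response_choice"] = labels[choices[ex]]
                    rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA)


def simulate_rating(design: ExperimentDesign, observers: list[ObserverModel],
                    seed: int | None = None, repeats_per_scale: int = 1) -> pd.DataFrame:
    """Rating task: one [0, 1] rating per observer x stimulus x scale block.

    The rating for scale ``s`` is the kernel probability of ``s`` for the
    stimulus cell, plus truncated Gaussian noise; a lapse replaces it by a
    uniform draw.  All observers see the same exemplar subset (the first
    ``stimuli_per_observer / 24`` per cell), mirroring a fixed stimulus
    set shared across participants.
    """
    if design.task != Task.RATING:
        raise ValueError("simulate_rating requires a rating design")
    rng = np.random.default_rng(seed)
    factor = design.rating_factor
    n_cells = len(design.materials) * len(design.transformations)
    n_ex_used = design.stimuli_per_observer // n_cells
    scales = design.rating_scales
    rows = []
    for obs in observers:
        kern = obs.kernels[factor]
        for mat in design.materials:
            for trans in design.transformations:
                p = kern.row(mat, trans)
                for ex in range(n_ex_used):
                    for s_idx, scale in enumerate(scales):
                        for _ in range(repeats_per_scale):
                            if rng.random() < obs.lapse_rate:
                                val = rng.random()
                            else:
                                val = p[s_idx] + rng.normal(0.0, obs.rating_noise_sd) \
                                    if obs.rating_noise_sd > 0 else p[s_idx]
                            row = _empty_row(obs.observer_id, Task.RATING.value,
                                             mat, trans, ex)
                            row["block_scale"] = scale
                            row["response_value"] = float(np.clip(val, 0.0, 1.0))
                            rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA)


def simulate_naming(design: ExperimentDesign, observers: list[ObserverModel],
                    lexicon: Lexicon, seed: int | None = None) -> pd.DataFrame:
    """Free naming: each observer sees one random exemplar per cell and
    answers two questions per stimulus (material name, transformation
    name), emitting lexicon strings for drawn categories.

    With probability ``oov_rate`` the emitted string falls outside the
    lexicon and will code to OTHER.
    """
    if design.task != Task.NAMING:
        raise ValueError("simulate_naming requires a naming design")
    rng = np.random.default_rng(seed)
    # canonical label -> the strings that code to it (label itself first)
    inverse: dict[str, list[str]] = {}
    for text, cat in lexicon.mapping.items():
        inverse.setdefault(cat, []).append(text)

    rows = []
    for obs in observers:
        for mat in design.materials:
            for trans in design.transformations:
                ex = int(rng.integers(design.n_exemplars))
                for factor, labels in (("material", design.materials),
                                       ("transformation", design.transformations)):
                    kern = obs.kernels[factor]
                    k = len(labels)
                    p = (1 - obs.lapse_rate) * kern.row(mat, trans) + obs.lapse_rate / k
                    cat = labels[int(rng.choice(k, p=p))]
                    if rng.random() < obs.oov_rate:
                        text = str(rng.choice(OOV_VOCABULARY))
                    else:
                        candidates = inverse.get(cat, [cat])
                        text = cat if cat in candidates else candidates[0]
                    row = _empty_row(obs.observer_id, Task.NAMING.value, mat, trans, ex)
                    row["block_scale"] = factor
                    row["response_text"] = text
                    rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA)
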