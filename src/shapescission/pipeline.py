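"""End-to-end pipeline runs: simulate or ingest, then analyze and report.

A :class:`RunConfig` fully determines a run — task, input source,
simulator parameters, seeds, resampling sizes — and serializes to YAML,
so a rerun from the same config is bit-identical.  Outputs (trial table,
confusion matrices, statistics JSON, manifest) are written under the
configured output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .design import ExperimentDesign, Task
from .trials import (Lexicon, code_naming_responses, ingest_deposited,
                     read_trials, validate_design, write_trials)
from .simulate import make_default_kernels, make_observers, simulate_afc, \
    simulate_naming, simulate_rating
from .confusion import afc_confusion, naming_confusion, per_observer_matrices, \
    rating_confusion, subgroup_matrices
from .perfstats import observer_consistency, performance_summary
from .rmanova import accuracy_cell_means, rm_anova_two_way
from .profile_space import build_profiles, label_separability, pca_profiles

TASKS = ("exp1_naming", "exp2_material", "exp2_transformation", "exp3_afc")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    task: str = "exp3_afc"
    input_csv: str | None = None  # None -> simulate
    seed: int = 0
    n_boot: int = 10_000
    n_null: int = 100_000
    null_kind: str = "uniform"
    out_dir: str = "runs/run0"
    # simulator parameters (used when input_csv is None)
    accuracy: float = 0.8
    confusability: float = 0.15
    material_modulation: dict = field(default_factory=lambda: {"wire": 2.0})
    lapse_rate: float = 0.02
    oov_rate: float = 0.1
    rating_noise_sd: float = 0.1
    observer_jitter_sd: float = 0.3
    n_observers: int = 15

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def design(self) -> ExperimentDesign:
        if self.task == "exp1_naming":
            return design_mod.naming_design(self.n_observers)
        if self.task == "exp2_material":
            return design_mod.rating_design("material", self.n_observers)
        if self.task == "exp2_transformation":
            return design_mod.rating_design("transformation", self.n_observers)
        return design_mod.afc_design(self.n_observers)


class StageError(RuntimeError):
    """An error in one pipeline stage, labeled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _simulate(config: RunConfig, dsg: ExperimentDesign, lexicon: Lexicon) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    kern_seed, obs_seed, sim_seed = (int(rng.integers(2**31)) for _ in range(3))
    kernels = []
    factors = {"exp1_naming": ("material", "transformation"),
               "exp2_material": ("material",),
               "exp2_transformation": ("transformation",),
               "exp3_afc": ("transformation",)}[config.task]
    for f in factors:
        kernels.append(make_default_kernels(
            dsg, response_factor=f, accuracy=config.accuracy,
            confusability=config.confusability if f == "transformation" else 0.0,
            material_modulation=config.material_modulation if f == "transformation" else None,
        ))
    observers = make_observers(
        kernels, dsg.n_observers, lapse_rate=config.lapse_rate,
        oov_rate=config.oov_rate, rating_noise_sd=config.rating_noise_sd,
        observer_jitter_sd=config.observer_jitter_sd, seed=obs_seed)
    if dsg.task == Task.NAMING:
        return simulate_naming(dsg, observers, lexicon, seed=sim_seed)
    if dsg.task == Task.RATING:
        return simulate_rating(dsg, observers, seed=sim_seed)
    return simulate_afc(dsg, observers, seed=sim_seed)


def run_pipeline(config: RunConfig, lexicon: Lexicon | None = None) -> dict:
    """Run simulate/ingest -> confusion -> stats (-> anova, pca) -> report.

    Returns the manifest: paths of written artifacts plus the summary
    statistics, with all seeds logged.  Any stage error is re-raised as a
    :class:`StageError` naming the stage; artifacts written before the
    failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dsg = config.design()
    lexicon = lexicon or Lexicon.default(dsg)
    manifest: dict = {"config": asdict(config), "stages": []}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - surfaced with stage label
            raise StageError(name, exc) from exc
        manifest["stages"].append(name)
        return result

    if config.input_csv is None:
        trials = stage("simulate", lambda: _simulate(config, dsg, lexicon))
    else:
        trials = stage("ingest", lambda: read_trials(config.input_csv, dsg))
    trials_path = out / "trials.csv"
    write_trials(trials, trials_path)
    manifest["trials_csv"] = str(trials_path)

    report = stage("validate", lambda: validate_design(trials, dsg))
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    manifest["validation_flags"] = report["n_flags"]

    rng = np.random.default_rng(config.seed + 1)
    stats_seed = int(rng.integers(2**31))

    if dsg.task == Task.NAMING:
        coded = stage("coding", lambda: code_naming_responses(trials, lexicon))
        for factor in ("material", "transformation"):
            cm = stage(f"confusion[{factor}]",
                       lambda f=factor: naming_confusion(coded, dsg, f))
            cm.to_csv(out / f"confusion_{factor}.csv")
            per_obs = [
                naming_confusion(g, dsg, factor)
                for _, g in coded.groupby("observer_id", sort=True)
            ]
            summary = stage(f"stats[{factor}]", lambda m=per_obs: performance_summary(
                m, n_boot=config.n_boot, n_null=config.n_null,
                seed=stats_seed, null_kind=config.null_kind))
            manifest[f"perf_{factor}"] = summary.to_dict()
    else:
        if dsg.task == Task.RATING:
            cm = stage("confusion", lambda: rating_confusion(trials, dsg))
        else:
            cm = stage("confusion", lambda: afc_confusion(trials, dsg))
        cm.to_csv(out / "confusion.csv")
        per_obs = list(per_observer_matrices(trials, dsg).values())
        summary = stage("stats", lambda: performance_summary(
            per_obs, n_boot=config.n_boot, n_null=config.n_null,
            seed=stats_seed, null_kind=config.null_kind))
        manifest["perf"] = summary.to_dict()
        manifest["consistency"] = observer_consistency(per_obs).to_dict()

        cells = stage("cell_means", lambda: accuracy_cell_means(trials, dsg))
        anova = stage("anova", lambda: rm_anova_two_way(cells))
        manifest["anova"] = anova.to_dict()
        (out / "anova.json").write_text(json.dumps(manifest["anova"], indent=1))

        subgroup_by = "material" if dsg.task == Task.AFC or \
            dsg.rating_factor == "transformation" else "transformation"
        subs = stage("subgroups", lambda: subgroup_matrices(trials, dsg, subgroup_by))
        for level, sub in subs.items():
            sub.to_csv(out / f"confusion_{subgroup_by}_{level.replace(' ', '_')}.csv")

        if dsg.task == Task.RATING:
            profiles = stage("profiles", lambda: build_profiles(trials, dsg))
            emb = stage("pca", lambda: pca_profiles(profiles))
            pd.DataFrame(emb.scores).to_csv(out / "pca_scores.csv", index=False)
            manifest["pca_explained_variance"] = emb.explained_variance_ratio.tolist()
            manifest["separability"] = {
                f: label_separability(emb, emb.labels(f))
                for f in ("material", "transformation")
            }

    manifest["seed"] = config.seed
    text = json.dumps(manifest, indent=1, sort_keys=True)
    (out / "manifest.json").write_text(text)
    manifest["manifest_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return manifest
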