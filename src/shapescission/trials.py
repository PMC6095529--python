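"""Long-format trial tables, CSV I/O, design validation and response coding.

A trial table holds one row per response event.  Columns:

``observer_id``
    Participant identifier (string).
``task``
    ``naming`` | ``rating`` | ``afc``.
``true_material``, ``true_transformation``
    Ground-truth categories of the photographed object.
``exemplar_id``
    Index of the execution/viewpoint within the cell (int).
``block_scale``
    For the rating task: the category scale of the block.  For the naming
    task: which question the row answers (``material`` or
    ``transformation``), since each naming trial asks for both.  Empty for
    forced choice.
``response_text`` / ``response_value`` / ``response_choice``
    Exactly one is populated, according to the task: free text, a rating
    in [0, 1], or the chosen category.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign, Task

SCHEMA = [
    "observer_id",
    "task",
    "true_material",
    "true_transformation",
    "exemplar_id",
    "block_scale",
    "response_text",
    "response_value",
    "response_choice",
]

_RESPONSE_COL = {
    Task.NAMING: "response_text",
    Task.RATING: "response_value",
    Task.AFC: "response_choice",
}

#: label of the bucket holding unmapped free-text responses
OTHER = "OTHER"


class TrialValidationError(ValueError):
    """A trial table violates the schema or the design's label sets."""


def _empty_text(s: pd.Series) -> pd.Series:
    return s.isna() | (s.astype("string").fillna("") == "")


def validate_trials(trials: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Check schema and per-row invariants; return the table unchanged.

    Raises :class:`TrialValidationError` naming the first offending row.
    """
    missing = [c for c in SCHEMA if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")

    for col, allowed in (
        ("true_material", set(design.materials)),
        ("true_transformation", set(design.transformations)),
    ):
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialValidationError(
                f"row {row}: unknown {col} {trials[col].iloc[row]!r}"
            )

    bad_task = ~trials["task"].isin([t.value for t in Task])
    if bad_task.any():
        row = int(np.flatnonzero(bad_task.to_numpy())[0])
        raise TrialValidationError(f"row {row}: unknown task {trials['task'].iloc[row]!r}")

    vals = pd.to_numeric(trials["response_value"], errors="coerce")
    has_val = vals.notna()
    out_of_range = has_val & ((vals < 0) | (vals > 1))
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise TrialValidationError(
            f"row {row}: response_value {vals.iloc[row]} outside [0, 1]"
        )

    populated = (
        (~_empty_text(trials["response_text"])).astype(int)
        + has_val.astype(int)
        + (~_empty_text(trials["response_choice"])).astype(int)
    )
    bad_pop = populated != 1
    if bad_pop.any():
        row = int(np.flatnonzero(bad_pop.to_numpy())[0])
        raise TrialValidationError(
            f"row {row}: exactly one response field must be populated "
            f"(found {populated.iloc[row]})"
        )

    # the populated field must match the task
    for task, col in _RESPONSE_COL.items():
        sel = trials["task"] == task.value
        if not sel.any():
            continue
        if col == "response_value":
            ok = has_val[sel]
        else:
            ok = ~_empty_text(trials.loc[sel, col])
        if not ok.all():
            row = int(np.flatnonzero((~ok).to_numpy())[0])
            raise TrialValidationError(
                f"{task.value} row lacks {col} (offending row {row} within task subset)"
            )
    return trials


def read_trials(path: str | Path, design: ExperimentDesign) -> pd.DataFrame:
    """Read and validate a trial-table CSV (UTF-8, comma-separated, header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        trials = pd.read_csv(
            path,
            dtype={
                "observer_id": "string", "task": "string",
                "true_material": "string", "true_transformation": "string",
                "block_scale": "string", "response_text": "string",
                "response_choice": "string",
            },
            keep_default_na=False,
            na_values=[""],
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise TrialValidationError(f"malformed CSV {path}: {exc}") from exc
    for col in ("block_scale", "response_text", "response_choice"):
        if col in trials.columns:
            trials[col] = trials[col].fillna("")
    return validate_trials(trials, design)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV with quoted free text."""
    import csv

    trials.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC, encoding="utf-8")


def validate_design(trials: pd.DataFrame, design: ExperimentDesign) -> dict:
    """Report per-observer cell coverage against the design.

    Returns a JSON-serializable report with one flag per deviation
    (missing cell, or unexpected repetition count).  Report-only; the
    data are never modified.
    """
    flags: list[dict] = []
    observers = (
        sorted(trials["observer_id"].unique())
        if len(trials)
        else [f"obs{i:02d}" for i in range(design.n_observers)]
    )
    # expected responses per (observer, material, transformation) cell
    cells_per_obs = design.stimuli_per_observer // (
        len(design.materials) * len(design.transformations)
    )
    per_cell = cells_per_obs * design.repetitions
    if design.task == Task.NAMING:
        per_cell *= 2  # material question + transformation question

    counts = (
        trials.groupby(["observer_id", "true_material", "true_transformation"])
        .size()
        .to_dict()
        if len(trials)
        else {}
    )
    for obs in observers:
        for m in design.materials:
            for t in design.transformations:
                n = counts.get((obs, m, t), 0)
                if n == 0:
                    flags.append(
                        {"observer": obs, "material": m, "transformation": t,
                         "problem": "missing cell", "count": 0, "expected": per_cell}
                    )
                elif n != per_cell:
                    flags.append(
                        {"observer": obs, "material": m, "transformation": t,
                         "problem": "repetition count", "count": int(n),
                         "expected": per_cell}
                    )
    return {
        "n_observers": len(observers),
        "expected_per_cell": per_cell,
        "n_flags": len(flags),
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# free-naming response coding


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip()).lower()


@dataclass
class Lexicon:
    """Mapping from normalized free-text strings to canonical categories.

    Strings with no mapping resolve to the literal ``OTHER`` bucket while
    retaining the original string for reporting.  Matching is
    case-insensitive after whitespace normalization.
    """

    mapping: dict[str, str]
    delimiter: str = ";"

    def __post_init__(self) -> None:
        self.mapping = {_normalize(k): v for k, v in self.mapping.items()}

    def lookup(self, text: str) -> tuple[str, str]:
        """Return ``(coded_category, original_string)``."""
        key = _normalize(text)
        return self.mapping.get(key, OTHER), text.strip()

    @classmethod
    def from_yaml(cls, path: str | Path, delimiter: str = ";") -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValueError(f"lexicon file {path} must hold a flat mapping")
        return cls({str(k): str(v) for k, v in mapping.items()}, delimiter)

    @classmethod
    def default(cls, design: ExperimentDesign, delimiter: str = ";") -> "Lexicon":
        """Identity mapping of the design labels plus common synonyms."""
        mapping = {lab: lab for lab in design.materials + design.transformations}
        synonyms = {
            "aluminium foil": "aluminum foil",
            "tin foil": "aluminum foil",
            "alu foil": "aluminum foil",
            "chicken wire": "wire",
            "wire mesh": "wire",
            "mesh": "wire",
            "modelling clay": "putty",
            "clay": "putty",
            "plasticine": "putty",
            "paperboard": "cardboard",
            "carton": "cardboard",
            "candle wax": "wax",
            "gold leaf": "gold foil",
            "twisted up": "twisted",
            "wrung": "twisted",
            "crumpled up": "crumpled",
            "scrunched": "crumpled",
            "scrunched up": "crumpled",
            "bent over": "bent",
            "folded up": "folded",
            "folded over": "folded",
        }
        labels = set(mapping)
        mapping.update({k: v for k, v in synonyms.items() if v in labels})
        return cls(mapping, delimiter)


def code_naming_responses(trials: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Code free-naming responses into canonical categories.

    Each ``response_text`` maps to a canonical label or to ``OTHER`` (the
    original string is kept in ``response_text``).  Responses containing
    the lexicon delimiter are split into multiple coded rows — the task
    instructions allowed several names per trial — and each split part
    counts as one response event.

    Idempotent: re-coding a coded table changes nothing.
    """
    if (trials["task"] != Task.NAMING.value).any():
        raise ValueError("code_naming_responses expects a naming-task table")

    out_rows = []
    for _, row in trials.iterrows():
        text = row["response_text"]
        parts = [p for p in str(text).split(lexicon.delimiter) if p.strip()]
        if not parts:
            parts = [str(text)]
        for part in parts:
            coded, original = lexicon.lookup(part)
            new = row.copy()
            new["response_text"] = original
            new["coded_category"] = coded
            out_rows.append(new)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return out


def ingest_deposited(path: str | Path, design: ExperimentDesign,
                     column_mapping: Mapping[str, str]) -> pd.DataFrame:
    """Adapt an externally deposited CSV to the trial-table schema.

    ``column_mapping`` maps schema column names to the deposited file's
    column names.  Unmapped schema columns that are optional for the task
    are filled with empty values; missing required columns raise.
    """
    raw = pd.read_csv(path, keep_default_na=False, na_values=[""])
    required = {"observer_id", "task", "true_material", "true_transformation"}
    table = pd.DataFrame()
    for schema_col in SCHEMA:
        src = column_mapping.get(schema_col, schema_col if schema_col in raw.columns else None)
        if src is not None:
            if src not in raw.columns:
                raise TrialValidationError(
                    f"mapped column {src!r} for {schema_col!r} not in file"
                )
            table[schema_col] = raw[src]
        elif schema_col in required:
            raise TrialValidationError(f"no mapping for required column {schema_col!r}")
        else:
            table[schema_col] = np.nan if schema_col == "response_value" else ""
    for col in ("block_scale", "response_text", "response_choice"):
        table[col] = table[col].fillna("").astype(str)
    table["observer_id"] = table["observer_id"].astype(str)
    return validate_trials(table, design)
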