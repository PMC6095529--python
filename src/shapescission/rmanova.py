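"""Two-way within-subject ANOVA with Huynh-Feldt sphericity correction.

The accuracy analyses treat every observer as their own control: each
observer contributes one accuracy value per material x transformation
cell, and both factors vary within subjects.  Sums of squares follow the
classical fully-within decomposition, each effect tested against its own
effect-by-subject interaction.  Sphericity (equal variances of all
pairwise condition differences) rarely holds with 6 and 4 levels, so the
degrees of freedom of each F test are multiplied by the Huynh-Feldt
epsilon estimated from that effect's orthonormal-contrast covariance
(capped at 1).  This matches the univariate repeated-measures output of
R's car::Anova.

Implemented from the formulas; library routines appear only as test
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign, Task


@dataclass(frozen=True)
class CellMeansTable:
    """Balanced observer x material x transformation accuracy grid."""

    observers: tuple[str, ...]
    materials: tuple[str, ...]
    transformations: tuple[str, ...]
    values: np.ndarray  # (n_observers, n_materials, n_transformations)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expect = (len(self.observers), len(self.materials), len(self.transformations))
        if v.shape != expect:
            raise ValueError(f"cell means shape {v.shape}, expected {expect}")
        if np.isnan(v).any():
            raise ValueError("cell means contain missing values")
        object.__setattr__(self, "values", v)

    def level_means(self, factor: str) -> pd.DataFrame:
        """Per-observer means of one factor, averaged over the other."""
        if factor == "material":
            m = self.values.mean(axis=2)
            labels = self.materials
        elif factor == "transformation":
            m = self.values.mean(axis=1)
            labels = self.transformations
        else:
            raise ValueError(f"unknown factor {factor!r}")
        return pd.DataFrame(m, index=list(self.observers), columns=list(labels))


def accuracy_cell_means(trials: pd.DataFrame, design: ExperimentDesign) -> CellMeansTable:
    """Accuracy per observer x material x transformation cell.

    * afc: proportion of correct transformation choices;
    * rating: mean rating on the true-category scale;
    * naming: proportion of coded responses matching the true category
      of the question asked (requires a coded table).

    Exemplars and repetitions are averaged out.  An unbalanced table
    (missing cells) is an error listing the missing cells.
    """
    task = Task(design.task)
    t = trials.copy()
    if task == Task.AFC:
        t["score"] = (t["response_choice"] == t["true_transformation"]).astype(float)
    elif task == Task.RATING:
        true_col = "true_material" if design.rating_factor == "material" \
            else "true_transformation"
        t = t[t["block_scale"] == t[true_col]].copy()
        t["score"] = t["response_value"].astype(float)
    else:
        if "coded_category" not in t.columns:
            raise ValueError("naming accuracy requires a coded table")
        true_for_question = np.where(
            t["block_scale"] == "material", t["true_material"], t["true_transformation"]
        )
        t["score"] = (t["coded_category"] == true_for_question).astype(float)

    observers = tuple(sorted(t["observer_id"].unique()))
    grid = t.groupby(["observer_id", "true_material", "true_transformation"])["score"].mean()
    values = np.full((len(observers), len(design.materials), len(design.transformations)), np.nan)
    missing = []
    for s, obs in enumerate(observers):
        for i, mat in enumerate(design.materials):
            for j, trans in enumerate(design.transformations):
                try:
                    values[s, i, j] = grid.loc[(obs, mat, trans)]
                except KeyError:
                    missing.append((obs, mat, trans))
    if missing:
        raise ValueError(f"unbalanced table; missing cells: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    return CellMeansTable(observers, tuple(design.materials),
                          tuple(design.transformations), values)


# ---------------------------------------------------------------------------
# Huynh-Feldt epsilon from orthonormal contrasts


def _ortho_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast basis of a k-level factor (k x (k-1))."""
    c = np.zeros((k, k - 1))
    for j in range(k - 1):
        c[: j + 1, j] = 1.0
        c[j + 1, j] = -(j + 1)
        c[:, j] /= np.linalg.norm(c[:, j])
    return c


def _epsilons(transformed: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and (capped) Huynh-Feldt epsilon.

    ``transformed`` is the n_subjects x df matrix of contrast scores for
    one effect; epsilon comes from its sample covariance.
    """
    n, d = transformed.shape
    s = np.atleast_2d(np.cov(transformed, rowvar=False, ddof=1))
    tr = np.trace(s)
    denom = d * np.sum(s ** 2)
    if denom <= 0:
        return 1.0, 1.0  # zero covariance: sphericity trivially holds
    gg = tr ** 2 / denom
    hf = (n * d * gg - 2.0) / (d * (n - 1.0 - d * gg))
    return float(gg), float(min(hf, 1.0))


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss_effect: float
    ss_error: float
    df_effect: float
    df_error: float
    eps_gg: float
    eps_hf: float
    f: float
    p_uncorrected: float
    p_hf: float

    @property
    def df_hf(self) -> tuple[float, float]:
        return (self.df_effect * self.eps_hf, self.df_error * self.eps_hf)

    def format(self) -> str:
        """Human-readable 'F(d1,d2) = F, p' line with HF-corrected dofs."""
        d1, d2 = self.df_hf
        p = "p < .001" if self.p_hf < 0.001 else f"p = {self.p_hf:.3f}".replace("0.", ".")
        return f"{self.name}: F({d1:.2f},{d2:.2f}) = {self.f:.2f}, {p}"


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectResult]
    ss_total: float
    ss_subjects: float

    def to_dict(self) -> dict:
        out = {"ss_total": self.ss_total, "ss_subjects": self.ss_subjects}
        for name, e in self.effects.items():
            out[name] = {
                "SS_effect": e.ss_effect, "SS_error": e.ss_error,
                "df": [e.df_effect, e.df_error],
                "eps_GG": e.eps_gg, "eps_HF": e.eps_hf,
                "df_HF": list(e.df_hf), "F": e.f,
                "p_uncorrected": e.p_uncorrected, "p_HF": e.p_hf,
            }
        return out


def rm_anova_two_way(cells: CellMeansTable,
                     factor_names: tuple[str, str] = ("material", "transformation")
                     ) -> AnovaResult:
    """Fully within-subject two-way ANOVA with HF-corrected p values.

    Each effect's F is MS_effect / MS_(effect x subject); its HF epsilon
    comes from the covariance of the effect's orthonormal contrast
    scores.  Zero error SS yields F = inf with p = 0 (degenerate data).
    """
    y = cells.values
    n, a, b = y.shape
    if n < 2:
        raise ValueError("at least 2 observers required")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(a * b * ((m_s - grand) ** 2).sum())
    ss_a = float(n * b * ((m_a - grand) ** 2).sum())
    ss_b = float(n * a * ((m_b - grand) ** 2).sum())
    ss_ab = float(n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = float(b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = float(a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = float(max(ss_abs, 0.0))

    ca, cb = _ortho_contrasts(a), _ortho_contrasts(b)
    one_a = np.ones((a, 1)) / np.sqrt(a)
    one_b = np.ones((b, 1)) / np.sqrt(b)
    ywide = y.reshape(n, a * b)  # material varies slowly, transformation fast

    effects = {}
    spec = [
        (factor_names[0], ss_a, ss_as, a - 1, (a - 1) * (n - 1), np.kron(ca, one_b)),
        (factor_names[1], ss_b, ss_bs, b - 1, (b - 1) * (n - 1), np.kron(one_a, cb)),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab, ss_abs,
         (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), np.kron(ca, cb)),
    ]
    for name, ss_e, ss_err, d1, d2, contrast in spec:
        gg, hf = _epsilons(ywide @ contrast)
        ms_e = ss_e / d1
        ms_err = ss_err / d2
        if ms_err == 0:
            f_val, p_unc, p_hf = float("inf"), 0.0, 0.0
        else:
            f_val = ms_e / ms_err
            p_unc = float(stats.f.sf(f_val, d1, d2))
            p_hf = float(stats.f.sf(f_val, d1 * hf, d2 * hf))
        effects[name] = EffectResult(name, ss_e, ss_err, d1, d2, gg, hf,
                                     float(f_val), p_unc, p_hf)
    return AnovaResult(effects, ss_total, ss_subj)


def posthoc_paired_t(cells: CellMeansTable, factor: str,
                     levels_pair: tuple[str, str]) -> dict:
    """Two-sided paired t test between two levels of one factor.

    Observer values are cell means averaged across the other factor; no
    multiple-comparison correction is applied (significance is flagged
    at the raw .05 and .001 levels).
    """
    means = cells.level_means(factor)
    for lev in levels_pair:
        if lev not in means.columns:
            raise ValueError(f"level {lev!r} not in factor {factor!r}")
    x = means[levels_pair[0]].to_numpy()
    y = means[levels_pair[1]].to_numpy()
    diff = x - y
    if np.ptp(diff) == 0:
        if np.allclose(diff, 0):
            # identical level means: no evidence of a difference
            return {"t": 0.0, "dof": len(diff) - 1, "p": 1.0,
                    "sig_05": False, "sig_001": False}
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(x, y)
    p = float(res.pvalue)
    return {"t": float(res.statistic), "dof": len(diff) - 1, "p": p,
            "sig_05": p < 0.05, "sig_001": p < 0.001}


def posthoc_all_pairs(cells: CellMeansTable, factor: str) -> pd.DataFrame:
    """Paired t tests for every unordered level pair of one factor."""
    import itertools

    labels = cells.materials if factor == "material" else cells.transformations
    rows = []
    for x, y in itertools.combinations(labels, 2):
        res = posthoc_paired_t(cells, factor, (x, y))
        rows.append({"level_a": x, "level_b": y, **res})
    return pd.DataFrame(rows)
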