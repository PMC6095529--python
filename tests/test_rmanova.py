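"""Two-way within-subject ANOVA: sums of squares, Huynh-Feldt epsilon,
F tests and post-hoc paired t tests, cross-checked against independent
routines (pingouin; R car::Anova when available)."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shapescission as sc
from shapescission.rmanova import CellMeansTable, rm_anova_two_way


def _random_table(rng, n=8, a=3, b=4, scale=1.0):
    y = rng.normal(size=(n, a, b)) * scale + rng.normal(size=(n, 1, 1))
    return CellMeansTable(tuple(f"o{i}" for i in range(n)),
                          tuple(f"m{i}" for i in range(a)),
                          tuple(f"t{j}" for j in range(b)), y)


def _long_format(cells):
    rows = []
    for s, obs in enumerate(cells.observers):
        for i, m in enumerate(cells.materials):
            for j, t in enumerate(cells.transformations):
                rows.append({"subj": obs, "A": m, "B": t,
                             "y": cells.values[s, i, j]})
    return pd.DataFrame(rows)


class TestCellMeans:
    def test_afc_proportion_correct(self, afc_trials, small_afc_design):
        cells = sc.accuracy_cell_means(afc_trials, small_afc_design)
        sub = afc_trials[(afc_trials["observer_id"] == "obs00")
                         & (afc_trials["true_material"] == "wax")
                         & (afc_trials["true_transformation"] == "bent")]
        expected = (sub["response_choice"] == "bent").mean()
        i = cells.materials.index("wax")
        j = cells.transformations.index("bent")
        assert cells.values[0, i, j] == pytest.approx(expected)

    def test_rating_true_scale_mean(self, rating_trials, small_rating_design):
        cells = sc.accuracy_cell_means(rating_trials, small_rating_design)
        sub = rating_trials[(rating_trials["observer_id"] == "obs00")
                            & (rating_trials["true_material"] == "wax")
                            & (rating_trials["true_transformation"] == "bent")
                            & (rating_trials["block_scale"] == "wax")]
        i = cells.materials.index("wax")
        j = cells.transformations.index("bent")
        assert cells.values[0, i, j] == pytest.approx(sub["response_value"].mean())

    def test_identity_kernels_give_all_ones(self, small_afc_design, identity_kernels):
        obs = sc.make_observers(identity_kernels, 4, seed=1)
        trials = sc.simulate_afc(small_afc_design, obs, seed=2)
        cells = sc.accuracy_cell_means(trials, small_afc_design)
        np.testing.assert_allclose(cells.values, 1.0)

    def test_unbalanced_table_lists_missing_cells(self, afc_trials, small_afc_design):
        broken = afc_trials[~((afc_trials["observer_id"] == "obs01")
                              & (afc_trials["true_material"] == "putty"))]
        with pytest.raises(ValueError, match="putty"):
            sc.accuracy_cell_means(broken, small_afc_design)


class TestAnovaBasics:
    def test_pure_subject_offsets_give_zero_f(self):
        rng = np.random.default_rng(1)
        offsets = rng.normal(size=(8, 1, 1))
        y = np.broadcast_to(offsets, (8, 3, 4)).copy()
        # condition means are identical; F = 0/0 handled as 0 effect SS
        cells = CellMeansTable(tuple(f"o{i}" for i in range(8)),
                               ("m0", "m1", "m2"), ("t0", "t1", "t2", "t3"), y)
        res = rm_anova_two_way(cells)
        for eff in res.effects.values():
            assert eff.ss_effect == pytest.approx(0.0, abs=1e-20)

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 2, 4))
        cells = CellMeansTable(tuple(f"o{i}" for i in range(8)),
                               ("m0", "m1"), ("t0", "t1", "t2", "t3"), y)
        res = rm_anova_two_way(cells)
        assert res.effects["material"].eps_gg == pytest.approx(1.0)
        assert res.effects["material"].eps_hf == pytest.approx(1.0)

    def test_ss_decomposition_is_complete(self, random_cells):
        res = rm_anova_two_way(random_cells)
        parts = res.ss_subjects + sum(e.ss_effect + e.ss_error
                                      for e in res.effects.values())
        assert parts == pytest.approx(res.ss_total, rel=1e-10)

    def test_location_invariance(self, random_cells):
        res = rm_anova_two_way(random_cells)
        shifted = CellMeansTable(random_cells.observers, random_cells.materials,
                                 random_cells.transformations,
                                 random_cells.values + 3.7)
        res2 = rm_anova_two_way(shifted)
        for name in res.effects:
            assert res2.effects[name].f == pytest.approx(res.effects[name].f)
            assert res2.effects[name].eps_hf == pytest.approx(res.effects[name].eps_hf)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cells = _random_table(rng, n=10, a=4, b=3)
            res = rm_anova_two_way(cells)
            for eff, k in (("material", 4), ("transformation", 3)):
                e = res.effects[eff]
                assert 1 / (k - 1) - 1e-9 <= e.eps_gg <= 1 + 1e-9
                assert e.eps_hf <= 1 + 1e-12

    def test_format_matches_reporting_style(self, random_cells):
        res = rm_anova_two_way(random_cells)
        line = res.effects["material"].format()
        assert line.startswith("material: F(")
        assert ", p" in line


class TestPingouinOracle:
    """SS, F, uncorrected p and main-effect epsilons against pingouin."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_way_ss_f_p(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        cells = _random_table(rng)
        res = rm_anova_two_way(cells)
        df = _long_format(cells)
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj",
                          detailed=True).set_index("Source")
        for mine, theirs in (("material", "A"), ("transformation", "B"),
                             ("material x transformation", "A * B")):
            e = res.effects[mine]
            assert e.ss_effect == pytest.approx(ref.loc[theirs, "SS"], abs=1e-9)
            assert e.f == pytest.approx(ref.loc[theirs, "F"], abs=1e-9)
            assert e.p_uncorrected == pytest.approx(ref.loc[theirs, "p_unc"], abs=1e-9)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_main_effect_epsilons(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        cells = _random_table(rng)
        res = rm_anova_two_way(cells)
        df = _long_format(cells)
        for mine, factor in (("material", "A"), ("transformation", "B")):
            agg = df.groupby(["subj", factor])["y"].mean().reset_index()
            for correction, attr in (("gg", "eps_gg"), ("hf", "eps_hf")):
                ref = pg.epsilon(agg, dv="y", within=factor, subject="subj",
                                 correction=correction)
                assert getattr(res.effects[mine], attr) == \
                    pytest.approx(min(ref, 1.0), abs=1e-9)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the car::Anova cross-check")
def test_full_hf_equivalence_against_r_car(tmp_path):
    """SS, GG/HF epsilon (including the interaction) and HF-corrected p
    match R car::Anova univariate repeated-measures output to 1e-6 on
    random balanced 8-subject 3x4 tables."""
    rng = np.random.default_rng(99)
    n_tables = 12
    tables = [_random_table(rng) for _ in range(n_tables)]
    stacked = np.stack([c.values.reshape(8, 12) for c in tables])
    np.savetxt(tmp_path / "tables.csv",
               stacked.reshape(n_tables * 8, 12), delimiter=",")
    script = tmp_path / "oracle.R"
    script.write_text("""
    suppressMessages(library(car))
    args <- commandArgs(trailingOnly=TRUE)
    x <- as.matrix(read.csv(args[1], header=FALSE))
    n_tables <- as.integer(args[2]); n <- 8
    idata <- expand.grid(B=factor(paste0("b",0:3)), A=factor(paste0("a",0:2)))
    idata <- idata[, c("A","B")]
    out <- list()
    for (k in 1:n_tables) {
      y <- x[((k-1)*n+1):(k*n), ]
      mod <- lm(y ~ 1)
      s <- summary(Anova(mod, idata=idata, idesign=~A*B, type=3),
                   multivariate=FALSE)
      ut <- s$univariate.tests
      pa <- s$pval.adjustments
      out[[k]] <- list(
        ss=unname(ut[2:4, "Sum Sq"]), ss_err=unname(ut[2:4, "Error SS"]),
        f=unname(ut[2:4, "F value"]), p=unname(ut[2:4, "Pr(>F)"]),
        gg=unname(pa[, "GG eps"]), hf=unname(pa[, "HF eps"]),
        p_hf=unname(pa[, "Pr(>F[HF])"]))
    }
    cat(jsonlite::toJSON(out, digits=12, auto_unbox=FALSE))
    """)
    proc = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "tables.csv"), str(n_tables)],
        capture_output=True, text=True, timeout=600)
    assert proc.returncode == 0, proc.stderr
    ref = json.loads(proc.stdout)

    order = ("material", "transformation", "material x transformation")
    for cells, r in zip(tables, ref):
        res = rm_anova_two_way(cells)
        for i, name in enumerate(order):
            e = res.effects[name]
            assert e.ss_effect == pytest.approx(r["ss"][i], abs=1e-6)
            assert e.ss_error == pytest.approx(r["ss_err"][i], abs=1e-6)
            assert e.f == pytest.approx(r["f"][i], abs=1e-6)
            assert e.p_uncorrected == pytest.approx(r["p"][i], abs=1e-6)
            assert e.eps_gg == pytest.approx(r["gg"][i], abs=1e-6)
            assert e.eps_hf == pytest.approx(min(r["hf"][i], 1.0), abs=1e-6)
            assert e.p_hf == pytest.approx(r["p_hf"][i], abs=1e-6)


class TestPosthoc:
    def test_identical_levels_give_t_zero(self):
        y = np.tile(np.linspace(0.4, 0.8, 5)[:, None, None], (1, 3, 4))
        cells = CellMeansTable(tuple(f"o{i}" for i in range(5)),
                               ("m0", "m1", "m2"), ("t0", "t1", "t2", "t3"), y)
        res = sc.posthoc_paired_t(cells, "material", ("m0", "m1"))
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_hand_computed_five_observer_example(self):
        """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n))."""
        d0 = np.array([0.9, 0.8, 0.85, 0.95, 0.7])
        d1 = np.array([0.6, 0.7, 0.65, 0.8, 0.5])
        y = np.zeros((5, 2, 4))
        y[:, 0, :] = d0[:, None]
        y[:, 1, :] = d1[:, None]
        cells = CellMeansTable(tuple(f"o{i}" for i in range(5)),
                               ("m0", "m1"), ("t0", "t1", "t2", "t3"), y)
        res = sc.posthoc_paired_t(cells, "material", ("m0", "m1"))
        diff = d0 - d1
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert res["t"] == pytest.approx(t_hand)
        assert res["p"] == pytest.approx(p_hand)
        assert res["dof"] == 4

    def test_dof_is_n_minus_one(self, random_cells):
        res = sc.posthoc_paired_t(random_cells, "transformation", ("t0", "t3"))
        assert res["dof"] == 7

    def test_all_pairs_count(self, random_cells):
        table = sc.posthoc_all_pairs(random_cells, "transformation")
        assert len(table) == 6

    def test_constant_nonzero_difference_is_error(self):
        y = np.zeros((4, 2, 2))
        y[:, 0, :] = 0.8
        y[:, 1, :] = 0.6
        cells = CellMeansTable(("a", "b", "c", "d"), ("m0", "m1"), ("t0", "t1"), y)
        with pytest.raises(ValueError, match="zero variance"):
            sc.posthoc_paired_t(cells, "material", ("m0", "m1"))
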