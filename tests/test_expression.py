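import numpy as np
import pandas as pd
import pytest

from glnreg.expression import (dependence, fold_changes, median_center,
                               read_expression_tsv, top_table,
                               two_way_anova_bh, write_expression_tsv)


def matrix_from_means(means, strains=("WT", "glnR"), n_reps=3, noise_sd=0.0,
                      seed=0):
    """Build a replicated log2 matrix from per-(gene, strain, timepoint) means.

    ``means`` maps gene -> {strain -> (T0, T30, T45)}.
    """
    rng = np.random.default_rng(seed)
    cols = pd.MultiIndex.from_tuples(
        [(s, tp, f"r{r}") for s in strains for tp in ("T0", "T30", "T45")
         for r in range(1, n_reps + 1)],
        names=("strain", "timepoint", "replicate"))
    rows = {}
    for gene, per_strain in means.items():
        vals = []
        for s, tp, _ in cols:
            base = dict(zip(("T0", "T30", "T45"), per_strain[s]))[tp]
            vals.append(base + (rng.normal(0, noise_sd) if noise_sd else 0))
        rows[gene] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


AMTB = {"WT": (0.0, np.log2(76.4), np.log2(76.4 / 15.0)),
        "glnR": (0.0, np.log2(1.1), np.log2(1.1))}
GLNA = {"WT": (2.0, 2.0 + np.log2(1.9), 2.0 + np.log2(1.9 / 1.7)),
        "glnR": (2.0, 2.0, 2.0)}
FLAT = {"WT": (5.0, 5.0, 5.0), "glnR": (5.0, 5.0, 5.0)}


class TestMedianCenter:
    def test_simple_row(self):
        m = matrix_from_means({"g": {"WT": (1, 2, 3), "glnR": (2, 2, 2)}},
                              n_reps=1)
        out = median_center(m)
        assert out.loc["g"].median() == 0

    def test_constant_row_becomes_zero(self):
        out = median_center(matrix_from_means({"g": FLAT}))
        assert (out.loc["g"] == 0).all()

    def test_every_output_row_median_is_zero(self, rng):
        cols = pd.MultiIndex.from_product(
            [("WT",), ("T0", "T30", "T45"), ("r1", "r2", "r3")],
            names=("strain", "timepoint", "replicate"))
        m = pd.DataFrame(rng.normal(size=(30, 9)), columns=cols)
        assert np.allclose(median_center(m).median(axis=1), 0)


class TestFoldChanges:
    def test_strong_target_fold_pair(self):
        calls = fold_changes(matrix_from_means({"amtB": AMTB}), "WT")
        assert calls.loc["amtB", "fold_induction"] == pytest.approx(76.4)
        assert calls.loc["amtB", "fold_repression"] == pytest.approx(15.0)
        assert calls.loc["amtB", "passes"]

    def test_near_threshold_gene_fails_dual_filter(self):
        calls = fold_changes(matrix_from_means({"glnA": GLNA}), "WT")
        assert calls.loc["glnA", "fold_induction"] == pytest.approx(1.9)
        assert calls.loc["glnA", "fold_repression"] == pytest.approx(1.7)
        assert not calls.loc["glnA", "passes"]

    def test_constant_gene_has_unit_folds(self):
        calls = fold_changes(matrix_from_means({"g": FLAT}), "WT")
        assert calls.loc["g", "fold_induction"] == 1.0
        assert calls.loc["g", "fold_repression"] == 1.0
        assert not calls.loc["g", "passes"]

    def test_missing_strain_or_cell_is_an_error(self):
        m = matrix_from_means({"g": FLAT})
        with pytest.raises(ValueError, match="glnRII"):
            fold_changes(m, "glnRII")
        incomplete = m.drop(columns=[("WT", "T45", r)
                                     for r in ("r1", "r2", "r3")])
        with pytest.raises(ValueError, match="T45"):
            fold_changes(incomplete, "WT")

    def test_invariant_under_median_centering(self, rng):
        m = matrix_from_means({"amtB": AMTB, "glnA": GLNA, "flat": FLAT},
                              noise_sd=0.3, seed=4)
        a = fold_changes(m, "WT")
        b = fold_changes(median_center(m), "WT")
        assert np.allclose(a["fold_induction"], b["fold_induction"])
        assert np.allclose(a["fold_repression"], b["fold_repression"])


class TestDependence:
    def test_wt_responsive_mutant_flat_is_dependent(self):
        calls = dependence(matrix_from_means({"amtB": AMTB}))
        assert calls.loc["amtB", "dependent"]

    def test_mutant_still_responding_is_not_dependent(self):
        both = {"WT": (0, np.log2(6.4), np.log2(6.4 / 7.5)),
                "glnR": (0, np.log2(6.0), np.log2(6.0 / 7.0))}
        calls = dependence(matrix_from_means({"g": both}))
        assert calls.loc["g", "wt_passes"]
        assert calls.loc["g", "mutant_passes"]
        assert not calls.loc["g", "dependent"]

    def test_dependent_implies_wt_passes_and_mutant_fails(self, rng):
        means = {f"g{i}": {"WT": tuple(rng.normal(5, 2, 3)),
                           "glnR": tuple(rng.normal(5, 2, 3))}
                 for i in range(60)}
        calls = dependence(matrix_from_means(means, noise_sd=0.2, seed=9))
        dep = calls[calls["dependent"]]
        assert dep["wt_passes"].all()
        assert not dep["mutant_passes"].any()

    def test_raising_theta_shrinks_the_dependent_set(self, rng):
        means = {f"g{i}": {"WT": (0, float(rng.uniform(0, 6)),
                                  float(rng.uniform(-2, 3))),
                           "glnR": (0, 0, 0)} for i in range(80)}
        m = matrix_from_means(means, noise_sd=0.1, seed=2)
        prev = None
        for theta in (1.5, 2.0, 3.0, 5.0, 8.0):
            dep = set(dependence(m, theta_wt=theta).query("dependent").index)
            if prev is not None:
                assert dep <= prev
            prev = dep

    def test_recovers_planted_dependent_genes_exactly(self):
        rng = np.random.default_rng(7)
        means = {}
        planted = [f"dep{i:03d}" for i in range(30)]
        for g in planted:
            ind = float(rng.uniform(2, 6))   # log2 units: >= 4-fold
            rep = float(rng.uniform(2, 4))
            means[g] = {"WT": (0, ind, ind - rep), "glnR": (0, 0, 0)}
        for i in range(200):
            means[f"null{i:03d}"] = {"WT": (0, 0, 0), "glnR": (0, 0, 0)}
        m = matrix_from_means(means, noise_sd=0.25, seed=7)
        calls = dependence(m)
        assert set(calls.query("dependent").index) == set(planted)


class TestAnova:
    def test_zero_variance_gene_gets_p_one(self):
        m = matrix_from_means({"g": FLAT}, n_reps=3)
        res = two_way_anova_bh(m)
        assert res.loc["g", "p_interaction"] == 1.0
        assert res.loc["g", "F_interaction"] == 0.0

    def test_hand_computed_two_by_two_sums_of_squares(self):
        # cells (WT,T0)=(1,2) (WT,T30)=(3,5) (mut,T0)=(2,2) (mut,T30)=(8,10)
        cols = pd.MultiIndex.from_tuples(
            [(s, tp, r) for s in ("WT", "mut") for tp in ("T0", "T30")
             for r in ("r1", "r2")], names=("strain", "timepoint",
                                            "replicate"))
        m = pd.DataFrame([[1, 2, 3, 5, 2, 2, 8, 10]], index=["g"],
                         columns=cols, dtype=float)
        res = two_way_anova_bh(m)
        # hand computation: SS_geno=15.125, SS_time=45.125, SS_int=10.125,
        # SSE=4.5 on 4 df -> F_int = 10.125 / 1.125 = 9.0
        assert res.loc["g", "F_interaction"] == pytest.approx(9.0)
        assert res.loc["g", "F_genotype"] == pytest.approx(15.125 / 1.125)
        assert res.loc["g", "F_time"] == pytest.approx(45.125 / 1.125)

    def test_agrees_with_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        cols = pd.MultiIndex.from_product(
            [("WT", "glnR"), ("T0", "T30", "T45"), ("r1", "r2", "r3")],
            names=("strain", "timepoint", "replicate"))
        m = pd.DataFrame(rng.normal(size=(5, 18)), columns=cols,
                         index=[f"g{i}" for i in range(5)])
        res = two_way_anova_bh(m)
        for g in m.index:
            data = pd.DataFrame({
                "y": m.loc[g].to_numpy(),
                "s": cols.get_level_values("strain"),
                "t": cols.get_level_values("timepoint")})
            tab = sm.stats.anova_lm(smf.ols("y ~ C(s) * C(t)", data).fit(),
                                    typ=2)
            assert res.loc[g, "F_interaction"] == pytest.approx(
                tab.loc["C(s):C(t)", "F"])
            assert res.loc[g, "p_genotype"] == pytest.approx(
                tab.loc["C(s)", "PR(>F)"])

    def test_single_level_factor_rejected(self):
        m = matrix_from_means({"g": FLAT}, strains=("WT",))
        with pytest.raises(ValueError, match="2 levels"):
            two_way_anova_bh(m)

    def test_bh_q_values_dominate_p_and_null_fdr_controlled(self):
        rng = np.random.default_rng(11)
        cols = pd.MultiIndex.from_product(
            [("WT", "glnR"), ("T0", "T30", "T45"), ("r1", "r2", "r3")],
            names=("strain", "timepoint", "replicate"))
        m = pd.DataFrame(rng.normal(size=(1000, 18)), columns=cols,
                         index=[f"g{i:04d}" for i in range(1000)])
        res = two_way_anova_bh(m)
        for effect in ("genotype", "time", "interaction"):
            p, q = res[f"p_{effect}"], res[f"q_{effect}"]
            assert (q >= p - 1e-12).all()
            # q is monotone non-decreasing in raw p order
            assert np.all(np.diff(
                q.to_numpy()[np.argsort(p.to_numpy())]) >= -1e-12)
            assert (q < 0.05).mean() <= 0.05


class TestTopTable:
    def _calls(self):
        return pd.DataFrame({
            "fold_induction": [10.0, 8.0, 8.0, 3.0, 1.2],
            "fold_repression": [5.0, 4.0, 3.0, 2.5, 1.0],
            "passes": [True, True, True, True, False],
        }, index=["gB", "gC", "gA", "gD", "gE"])

    def test_sorted_by_induction_with_lexical_tie_break(self):
        top = top_table(self._calls(), n=3)
        assert list(top.index) == ["gB", "gA", "gC"]

    def test_n_larger_than_passing_set_returns_whole_set(self):
        assert len(top_table(self._calls(), n=50)) == 4

    def test_annotation_columns_joined(self):
        ann = pd.DataFrame({"homologue": ["SCO1", "SCO2"]},
                           index=["gB", "gC"])
        top = top_table(self._calls(), n=2, annotation=ann)
        assert top.loc["gB", "homologue"] == "SCO1"


class TestIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        m = matrix_from_means({"amtB": AMTB, "flat": FLAT}, noise_sd=0.2,
                              seed=3)
        write_expression_tsv(m, tmp_path / "m.tsv")
        again = read_expression_tsv(tmp_path / "m.tsv")
        assert np.allclose(again.to_numpy(), m.to_numpy())
        assert list(again.columns) == list(m.columns)
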