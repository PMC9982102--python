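import numpy as np
import pandas as pd
import pytest

from heteropeus.heterosis import (
    ANOVA_SOURCES,
    CombiningAbility,
    anova_line_tester,
    combining_ability,
    compute_heterosis,
    error_row,
    lsd,
)
from heteropeus.scoring import CrossDesign, cross_id


def make_design(n_lines=2, n_testers=2):
    lines = [f"L{i}" for i in range(1, n_lines + 1)]
    testers = [f"T{j}" for j in range(1, n_testers + 1)]
    return CrossDesign(
        crosses=[(f, m) for f in lines for m in testers],
        roles={**{s: "line" for s in lines}, **{s: "tester" for s in testers}},
    )


def balanced_plots(design, value, n_loc=1, n_reps=1, parents=True):
    """Plot table where `value(entry_id, loc, rep)` gives the yield."""
    rows = []
    entries = [(cross_id(f, m), "F1") for f, m in design.crosses]
    if parents:
        entries += [(p, "parent") for p in design.parents]
    for eid, etype in entries:
        for l in range(n_loc):
            for k in range(n_reps):
                rows.append(
                    {
                        "entry_id": eid,
                        "entry_type": etype,
                        "location": f"Loc{l + 1}",
                        "replication": k + 1,
                        "gy": float(value(eid, l, k)),
                    }
                )
    return pd.DataFrame(rows)


class TestComputeHeterosis:
    def test_formula_toy_case(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {"P1xP2": 10.0, "P1": 8.0, "P2": 6.0}
        plots = balanced_plots(design, lambda e, l, k: vals[e])
        het = compute_heterosis(plots, design).iloc[0]
        assert het["mp"] == 7.0
        assert het["bp"] == 8.0
        assert het["mph"] == pytest.approx(100 * 3 / 7)   # 42.857...
        assert het["bph"] == pytest.approx(25.0)

    def test_f1_equal_to_midparent_gives_zero_mph(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {"P1xP2": 7.0, "P1": 8.0, "P2": 6.0}
        het = compute_heterosis(balanced_plots(design, lambda e, l, k: vals[e]), design)
        assert het["mph"].iloc[0] == pytest.approx(0.0)

    def test_equal_parents_make_mph_equal_bph(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {"P1xP2": 9.0, "P1": 6.0, "P2": 6.0}
        het = compute_heterosis(balanced_plots(design, lambda e, l, k: vals[e]), design)
        assert het["mph"].iloc[0] == het["bph"].iloc[0] == pytest.approx(50.0)

    def test_bph_at_most_mph_for_positive_unequal_parents(self, rng):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        for _ in range(50):
            p1, p2 = rng.uniform(1, 10, 2)
            f1 = rng.uniform(0.1, 20)
            vals = {"P1xP2": f1, "P1": p1, "P2": p2}
            het = compute_heterosis(balanced_plots(design, lambda e, l, k: vals[e]), design)
            if p1 != p2:
                assert het["bph"].iloc[0] < het["mph"].iloc[0]

    def test_nonpositive_parent_mean_flagged_not_fabricated(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {"P1xP2": 5.0, "P1": 0.0, "P2": 0.0}
        het = compute_heterosis(balanced_plots(design, lambda e, l, k: vals[e]), design)
        assert not het["defined"].iloc[0]
        assert np.isnan(het["mph"].iloc[0])

    def test_per_location_scope_averages_within_location(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {("P1xP2", 0): 10.0, ("P1xP2", 1): 8.0,
                ("P1", 0): 8.0, ("P1", 1): 8.0, ("P2", 0): 6.0, ("P2", 1): 4.0}
        plots = balanced_plots(design, lambda e, l, k: vals[(e, l)], n_loc=2, n_reps=2)
        het = compute_heterosis(plots, design, scope="per-location")
        assert len(het) == 2
        loc1 = het[het["location"] == "Loc1"].iloc[0]
        assert loc1["mph"] == pytest.approx(100 * 3 / 7)
        loc2 = het[het["location"] == "Loc2"].iloc[0]
        assert loc2["mph"] == pytest.approx(100 * 2 / 6)

    def test_missing_parent_phenotype_raises(self):
        design = CrossDesign(crosses=[("P1", "P2")], roles={"P1": "line", "P2": "tester"})
        vals = {"P1xP2": 5.0, "P1": 4.0, "P2": 4.0}
        plots = balanced_plots(design, lambda e, l, k: vals[e])
        plots = plots[plots["entry_id"] != "P2"]
        with pytest.raises(ValueError, match="P2"):
            compute_heterosis(plots, design)


class TestAnova:
    def test_trial_layout_degrees_of_freedom(self, rng):
        design = make_design(19, 5)
        plots = balanced_plots(
            design, lambda e, l, k: rng.normal(8, 1), n_loc=3, n_reps=3, parents=False
        )
        anova = anova_line_tester(plots, design)
        assert list(anova["source"]) == ANOVA_SOURCES
        assert list(anova["df"]) == [2, 6, 18, 4, 72, 36, 8, 144, 564]

    def test_sum_of_squares_conservation(self, rng):
        design = make_design(2, 2)
        plots = balanced_plots(
            design, lambda e, l, k: rng.normal(5, 2), n_loc=2, n_reps=2, parents=False
        )
        anova = anova_line_tester(plots, design)
        total = ((plots["gy"] - plots["gy"].mean()) ** 2).sum()
        assert anova["sum_sq"].sum() == pytest.approx(total, rel=1e-12)
        assert np.allclose(anova["mean_sq"], anova["sum_sq"] / anova["df"])

    def test_constant_data_zero_model_ss(self):
        design = make_design(2, 2)
        plots = balanced_plots(design, lambda e, l, k: 4.2, n_loc=2, n_reps=2, parents=False)
        anova = anova_line_tester(plots, design)
        assert anova["sum_sq"].abs().max() == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("shape", [(3, 3, 2, 2), (2, 3, 2, 2), (3, 2, 2, 3)])
    def test_matches_statsmodels_sequential_anova(self, shape, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        L, T, E, R = shape
        design = make_design(L, T)
        plots = balanced_plots(
            design, lambda e, l, k: rng.normal(6, 1.5), n_loc=E, n_reps=R, parents=False
        )
        anova = anova_line_tester(plots, design).set_index("source")

        df = plots.copy()
        df[["line", "tester"]] = df["entry_id"].str.split("x", expand=True)
        model = smf.ols(
            "gy ~ C(location) + C(location):C(replication) + C(line) + C(tester)"
            " + C(line):C(tester) + C(line):C(location) + C(tester):C(location)"
            " + C(line):C(tester):C(location)",
            data=df,
        ).fit()
        table = sm.stats.anova_lm(model, typ=1)
        mapping = {
            "C(location)": "Locations (Loc)",
            "C(location):C(replication)": "Replications:Loc",
            "C(line)": "Lines",
            "C(tester)": "Testers (T)",
            "C(line):C(tester)": "Lines x T",
            "C(line):C(location)": "Lines x Loc",
            "C(tester):C(location)": "T x Loc",
            "C(line):C(tester):C(location)": "Lines x T x Loc",
            "Residual": "Error",
        }
        for sm_name, ours in mapping.items():
            assert table.loc[sm_name, "sum_sq"] == pytest.approx(
                anova.loc[ours, "sum_sq"], abs=1e-9
            ), ours
            assert int(table.loc[sm_name, "df"]) == int(anova.loc[ours, "df"])

    def test_f_tests_use_error_mean_square(self, rng):
        design = make_design(3, 2)
        plots = balanced_plots(
            design, lambda e, l, k: rng.normal(6, 1), n_loc=2, n_reps=2, parents=False
        )
        anova = anova_line_tester(plots, design).set_index("source")
        ms_err, _ = error_row(anova.reset_index())
        for source in ANOVA_SOURCES[:-1]:
            assert anova.loc[source, "F"] == pytest.approx(
                anova.loc[source, "mean_sq"] / ms_err
            )

    def test_unbalanced_data_rejected(self, rng):
        design = make_design(2, 2)
        plots = balanced_plots(
            design, lambda e, l, k: rng.normal(6, 1), n_loc=2, n_reps=2, parents=False
        )
        with pytest.raises(ValueError, match="balanced"):
            anova_line_tester(plots.iloc[:-1], design)


class TestLsd:
    def anova_with_error(self, ms, df):
        return pd.DataFrame(
            [{"source": "Error", "df": df, "sum_sq": ms * df, "mean_sq": ms,
              "F": np.nan, "p": np.nan}]
        )

    def test_reported_error_term_value(self):
        # MS_error = 2.63 on 564 df, means over 9 plots:
        # t(0.975, 564) = 1.9641790 (scipy and R's qt agree)
        anova = self.anova_with_error(2.63, 564)
        assert lsd(anova, n_per_mean=9) == pytest.approx(1.5015945616, abs=1e-9)

    def test_larger_alpha_shrinks_lsd(self):
        anova = self.anova_with_error(2.0, 100)
        assert lsd(anova, 4, alpha=0.10) < lsd(anova, 4, alpha=0.05)

    def test_zero_error_ms_gives_zero(self):
        assert lsd(self.anova_with_error(0.0, 50), 3) == 0.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            lsd(self.anova_with_error(1.0, 50), 0)


class TestCombiningAbility:
    def plots_from_means(self, means):
        means = np.asarray(means, dtype=float)
        design = make_design(*means.shape)
        return design, balanced_plots(
            design,
            lambda e, l, k: means[
                int(e.split("x")[0][1:]) - 1, int(e.split("x")[1][1:]) - 1
            ],
            parents=False,
        )

    def test_additive_table_has_zero_sca(self):
        design, plots = self.plots_from_means([[4, 6], [6, 8]])
        ca = combining_ability(plots, design)
        assert list(ca.gca_line) == [-1, 1]
        assert list(ca.gca_tester) == [-1, 1]
        assert np.allclose(ca.sca, 0)

    def test_constant_means_zero_effects(self):
        design, plots = self.plots_from_means([[5, 5], [5, 5]])
        ca = combining_ability(plots, design)
        assert np.allclose(ca.gca_line, 0) and np.allclose(ca.sca, 0)

    def test_interaction_pattern_sca(self):
        design, plots = self.plots_from_means([[4, 6], [8, 6]])
        ca = combining_ability(plots, design)
        assert np.allclose(ca.sca.values, [[-1, 1], [1, -1]])

    def test_effects_sum_to_zero_and_reconstruct(self, rng):
        means = rng.normal(8, 2, size=(4, 3))
        design, plots = self.plots_from_means(means)
        ca = combining_ability(plots, design)
        assert ca.gca_line.sum() == pytest.approx(0, abs=1e-12)
        assert ca.gca_tester.sum() == pytest.approx(0, abs=1e-12)
        assert np.allclose(ca.sca.sum(axis=0), 0) and np.allclose(ca.sca.sum(axis=1), 0)
        for i, line in enumerate(design.lines):
            for j, tester in enumerate(design.testers):
                assert ca.reconstruct(line, tester) == pytest.approx(means[i, j])
        assert isinstance(ca, CombiningAbility)
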