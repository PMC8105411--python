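"""ANCOVA densitometry, foci summaries, t-tests and Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4screen import assay_stats as ast
from g4screen.simulate import simulate_blot


class TestAncova:
    def test_zero_noise_exact_recovery(self):
        df = simulate_blot(
            noise_sd=0.0, beta_load=1.3,
            genotype_effects={"KO": -1.0},
            treatment_effects={"drug": 0.5},
            interaction_effects={("KO", "drug"): 0.25},
            lanes_per_cell=3, seed=1,
        )
        res = ast.ancova_blot(df)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-18)
        coef = res.coefficients
        assert coef["_load"] == pytest.approx(1.3, abs=1e-8)
        terms = {t: v for t, v in zip(res.contrasts["term"],
                                      res.contrasts["log2_difference"])}
        ko = [v for t, v in terms.items() if "T.KO]" in t and ":" not in t]
        assert ko[0] == pytest.approx(-1.0, abs=1e-8)

    def test_sequential_ss_sum_to_total(self):
        df = simulate_blot(noise_sd=0.4, genotype_effects={"KO": -0.8},
                           lanes_per_cell=3, seed=4)
        res = ast.ancova_blot(df)
        tab = res.anova_table
        y = np.log2(df["signal"])
        total_ss = ((y - y.mean()) ** 2).sum()
        assert tab["Sum Sq"].sum() == pytest.approx(total_ss, rel=1e-10)

    def test_table_order_covariate_first(self):
        df = simulate_blot(noise_sd=0.2, seed=0, lanes_per_cell=3)
        res = ast.ancova_blot(df)
        assert list(res.anova_table.index) == [
            "log2_loading", "genotype", "treatment",
            "genotype:treatment", "Residual",
        ]

    def test_orthogonal_design_sequential_equals_marginal(self):
        """Balanced design, covariate centered per cell: Type I == marginal.

        The oracle computes each term's marginal SS from normal equations
        (residual-SS drop when the term is removed from the full model).
        """
        rng = np.random.default_rng(6)
        rows = []
        lane = 0
        # loading pattern symmetric within every genotype x treatment cell
        for g in ("WT", "KO"):
            for t in ("vehicle", "drug"):
                for delta in (-0.5, 0.5):
                    lane += 1
                    log2_load = 10 + delta
                    y = (
                        1.0
                        + 0.9 * log2_load
                        + (0.7 if g == "KO" else 0)
                        + (-0.4 if t == "drug" else 0)
                        + rng.normal(0, 0.3)
                    )
                    rows.append((f"l{lane}", 2.0**y, 2.0**log2_load, g, t))
        df = pd.DataFrame(rows, columns=["lane", "signal", "loading",
                                         "genotype", "treatment"])
        res = ast.ancova_blot(df)
        tab = res.anova_table

        # normal-equations oracle via numpy lstsq on explicit design columns;
        # factors are sum-to-zero coded so that, in this balanced design with
        # a per-cell-centered covariate, all term subspaces are orthogonal and
        # marginal SS are well defined with the interaction retained
        yv = np.log2(df["signal"].to_numpy())
        load = np.log2(df["loading"].to_numpy())
        gcol = np.where(df["genotype"] == "KO", 1.0, -1.0)
        tcol = np.where(df["treatment"] == "drug", 1.0, -1.0)
        inter = gcol * tcol
        ones = np.ones_like(yv)

        def rss(*cols):
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            return float(np.sum((yv - X @ beta) ** 2))

        full = [ones, load, gcol, tcol, inter]
        marginal = {
            "log2_loading": rss(ones, gcol, tcol, inter) - rss(*full),
            "genotype": rss(ones, load, tcol, inter) - rss(*full),
            "treatment": rss(ones, load, gcol, inter) - rss(*full),
        }
        for term, ss in marginal.items():
            assert tab.loc[term, "Sum Sq"] == pytest.approx(ss, rel=1e-8)

    def test_true_null_treatment_p_uniform(self):
        """Permutation-style calibration: null treatment F-test p ~ U(0,1)."""
        ps = []
        for s in range(200):
            df = simulate_blot(
                noise_sd=0.4, genotype_effects={"KO": -0.5},
                treatment_effects={}, lanes_per_cell=3, seed=1000 + s,
            )
            res = ast.ancova_blot(df)
            ps.append(res.anova_table.loc["treatment", "Pr(>F)"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_nonpositive_density_rejected(self):
        df = simulate_blot(seed=0)
        df.loc[0, "signal"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            ast.ancova_blot(df)

    def test_fold_change_is_two_to_coefficient(self):
        df = simulate_blot(noise_sd=0.3, genotype_effects={"KO": -1.0},
                           lanes_per_cell=3, seed=9)
        res = ast.ancova_blot(df)
        for _, row in res.contrasts.iterrows():
            assert row["fold_change"] == pytest.approx(
                2.0 ** row["log2_difference"]
            )
            assert row["fold_ci_lower"] <= row["fold_change"] <= row["fold_ci_upper"]


class TestFoci:
    def _table(self, counts, marker="FK2", condition="drug"):
        return pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(len(counts))],
                "marker": marker,
                "foci_count": counts,
                "overlap_count": [0] * len(counts),
                "condition": condition,
            }
        )

    def test_fk2_threshold_boundary(self):
        table = self._table([10, 9])
        out = ast.foci_positive(table)
        assert out["percent_positive"].iloc[0] == pytest.approx(50.0)

    def test_all_zero_counts(self):
        out = ast.foci_positive(self._table([0, 0, 0]))
        assert out["percent_positive"].iloc[0] == 0.0

    def test_mixed_table_manual_count(self):
        table = self._table([0, 3, 5, 9, 10, 25])
        out = ast.foci_positive(table)  # FK2 threshold 10 -> 2 of 6
        assert out["percent_positive"].iloc[0] == pytest.approx(100 * 2 / 6)
        assert out["n_cells"].iloc[0] == 6

    def test_missing_threshold_rejected(self):
        with pytest.raises(KeyError):
            ast.foci_positive(self._table([1], marker="BG4"))

    @pytest.mark.parametrize("thr", [1, 3, 5, 10, 20])
    def test_monotone_in_threshold(self, thr, rng):
        counts = rng.poisson(6, size=60).tolist()
        lo = ast.foci_positive(self._table(counts), {"FK2": thr})
        hi = ast.foci_positive(self._table(counts), {"FK2": thr + 1})
        assert hi["percent_positive"].iloc[0] <= lo["percent_positive"].iloc[0]


class TestColocalization:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["cell", "marker", "foci_count", "overlap_count",
                           "condition"]
        )

    def test_full_overlap_both_directions(self):
        t = self._table([
            ("c1", "FK2", 7, 7, "drug"),
            ("c1", "BG4", 4, 4, "drug"),
        ])
        out = ast.colocalization(t, "FK2", "BG4")
        assert (out["percent_overlap"] == 100.0).all()

    def test_asymmetric_directions(self):
        t = self._table([
            ("c1", "A", 10, 4, "drug"),
            ("c1", "B", 8, 4, "drug"),
        ])
        out = ast.colocalization(t, "A", "B").set_index("direction")
        assert out.loc["A+B", "percent_overlap"] == pytest.approx(40.0)
        assert out.loc["B+A", "percent_overlap"] == pytest.approx(50.0)

    def test_random_table_vs_brute_force(self, rng):
        rows = []
        for i in range(30):
            total = int(rng.integers(1, 20))
            rows.append((f"c{i}", "A", total, int(rng.integers(0, total + 1)),
                         "drug"))
        t = self._table(rows)
        out = ast.colocalization(t, "A", "B")
        oracle = np.mean([100 * r[3] / r[2] for r in rows])
        got = out.set_index("direction").loc["A+B", "percent_overlap"]
        assert got == pytest.approx(oracle)

    def test_overlap_exceeding_total_rejected(self):
        t = self._table([("c1", "A", 3, 5, "drug")])
        with pytest.raises(ValueError, match="exceeds"):
            ast.colocalization(t, "A", "B")


class TestTests:
    def test_identical_samples(self):
        t, p = ast.two_sample_tests([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_welch_equals_student_for_equal_n_and_var(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.5, 3.5, 4.5, 5.5]  # same spread, shifted
        _, p_s = ast.two_sample_tests(x, y, mode="student")
        _, p_w = ast.two_sample_tests(x, y, mode="welch")
        assert p_w == pytest.approx(p_s, rel=1e-12)

    def test_constant_samples_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ast.two_sample_tests([1.0, 1.0], [2.0, 2.0])

    def test_tukey_two_groups_equals_t_test(self):
        """q = t*sqrt(2): with 2 groups Tukey reduces to the pooled t."""
        x = [3.1, 2.9, 3.4, 3.3]
        y = [3.9, 4.2, 3.8, 4.4]
        out = ast.tukey_hsd({"a": x, "b": y})
        _, p_oracle = stats.ttest_ind(x, y, equal_var=True)
        assert out["p_adjusted"].iloc[0] == pytest.approx(p_oracle, rel=1e-6)

    def test_tukey_three_groups_adjusted_vs_scipy(self):
        groups = {"a": [1.0, 1.2, 0.8], "b": [1.1, 1.3, 0.9], "c": [2.0, 2.2, 1.8]}
        out = ast.tukey_hsd(groups)
        oracle = stats.tukey_hsd(*groups.values())
        got = out.set_index(["group_a", "group_b"])["p_adjusted"]
        assert got.loc[("a", "b")] == pytest.approx(oracle.pvalue[0, 1], abs=1e-8)
        assert got.loc[("a", "c")] == pytest.approx(oracle.pvalue[0, 2], abs=1e-8)
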