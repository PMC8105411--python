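"""Generator structure, seed determinism, and effect-recovery oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import poisson

from g4screen import simulate as sim
from g4screen.pharm import FourPLParams, four_pl


class TestScreenSim:
    def test_default_library_composition(self):
        cfg = sim.ScreenSimConfig(seed=0)
        data = sim.simulate_screen(cfg)
        assert data.counts.counts.shape[0] == 2930
        lib = data.library.entries
        assert (~lib["is_nt"]).sum() == 480 * 6
        assert lib["is_nt"].sum() == 50

    def test_seed_determinism(self):
        cfg = sim.ScreenSimConfig(n_genes=20, seed=42)
        a = sim.simulate_screen(cfg)
        b = sim.simulate_screen(cfg)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        assert a.essential_genes == b.essential_genes

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sim.ScreenSimConfig(depth=0)
        with pytest.raises(ValueError):
            sim.ScreenSimConfig(dispersion=-1)

    def test_null_screen_neutral_drift(self):
        """With zero lfc, 'essential' genes drift like non-targeting guides."""
        cfg = sim.ScreenSimConfig(
            n_genes=60, essential_fraction=0.2, essential_lfc=0.0,
            depth=800, seed=11,
        )
        data = sim.simulate_screen(cfg)
        cm = data.counts
        day1 = cm.counts[cm.select(day=1, condition="vehicle")].mean(axis=1)
        day19 = cm.counts[cm.select(day=19, condition="vehicle")].mean(axis=1)
        lfc = np.log2((day19 + 0.5) / (day1 + 0.5))
        gene = data.library.entries.set_index("sgrna_id")["gene"]
        is_nt = data.library.entries.set_index("sgrna_id")["is_nt"]
        planted = lfc[gene.isin(data.essential_genes).to_numpy()]
        neutral = lfc[is_nt.to_numpy()]
        se = np.sqrt(planted.var() / len(planted) + neutral.var() / len(neutral))
        assert abs(planted.mean() - neutral.mean()) < 4 * se

    def test_planted_lfc_vs_nb_sampling_oracle(self):
        """-1 log2/passage over 4 passages gives ~-4, vs direct NB resampling.

        The oracle draws 10k NB count pairs at the generative means
        (including the compositional renormalization factor implied by
        the config) and computes the expected observed mean log2 ratio.
        """
        cfg = sim.ScreenSimConfig(
            n_genes=100, guides_per_gene=6, n_nontargeting=50,
            essential_fraction=0.05, essential_lfc=-1.0,
            depth=1000, dispersion=1000.0, abundance_sigma=0.0,
            timepoints=(1, 19), passage_days=(4, 8, 12, 16), replicates=2,
            seed=5,
        )
        assert cfg.passages_by(19) == 4
        data = sim.simulate_screen(cfg)
        cm = data.counts
        day1 = cm.counts[cm.select(day=1, condition="vehicle")].mean(axis=1)
        day19 = cm.counts[cm.select(day=19, condition="vehicle")].mean(axis=1)
        gene = data.library.entries.set_index("sgrna_id")["gene"]
        mask = gene.isin(data.essential_genes).to_numpy()
        observed = np.log2((day19[mask] + 0.5) / (day1[mask] + 0.5)).mean()

        # oracle: renormalization factor from first principles
        n_ess_guides = len(data.essential_genes) * cfg.guides_per_gene
        frac = n_ess_guides / cfg.n_guides_total
        mass19 = 1 - frac + frac * 2.0**-4
        mean1 = cfg.depth
        mean19 = cfg.depth * 2.0**-4 / mass19
        rng = np.random.default_rng(999)
        draws = 10_000
        c1 = rng.negative_binomial(1000, 1000 / (1000 + mean1), size=draws)
        c19 = rng.negative_binomial(1000, 1000 / (1000 + mean19), size=draws)
        oracle_vals = np.log2((c19 + 0.5) / (c1 + 0.5))
        oracle = oracle_vals.mean()
        se = oracle_vals.std(ddof=1) / np.sqrt(min(draws, mask.sum()))
        assert observed == pytest.approx(oracle, abs=4 * se)
        assert observed == pytest.approx(-4.0, abs=0.2)

    def test_drug_interaction_only_in_matching_arm(self):
        cfg = sim.ScreenSimConfig(
            n_genes=30, essential_fraction=0.0, depth=2000, dispersion=200,
            interacting_genes=(("GENE0003", "drugA", -1.5),),
            abundance_sigma=0.0, seed=2,
        )
        data = sim.simulate_screen(cfg)
        cm = data.counts
        gene = data.library.entries.set_index("sgrna_id")["gene"]
        mask = (gene == "GENE0003").to_numpy()
        drug19 = cm.counts[cm.select(day=19, condition="drugA")].mean(axis=1)
        veh19 = cm.counts[cm.select(day=19, condition="vehicle")].mean(axis=1)
        lfc = np.log2((drug19 + 0.5) / (veh19 + 0.5))
        assert lfc[mask].mean() < -5  # -1.5 x 5 passages, plus renormalization
        assert abs(lfc[~mask].mean()) < 0.5


class TestCgaSim:
    def test_null_logit_difference(self):
        cfg = sim.CgaSimConfig(drug_effects={"drug": 0.0}, seed=1)
        diffs = []
        for s in range(300):
            exp = sim.simulate_cga(sim.CgaSimConfig(drug_effects={"drug": 0.0}, seed=s))
            d = exp.data
            diffs.append(
                logit(d.loc[d.condition == "drug", "proportion"]).mean()
                - logit(d.loc[d.condition == "vehicle", "proportion"]).mean()
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se

    def test_noise_free_exact(self):
        cfg = sim.CgaSimConfig(
            assay_sd=0.0, replicate_sd=0.0, baseline_logit=-0.5,
            drug_effects={"drug": -1.0}, seed=0,
        )
        exp = sim.simulate_cga(cfg)
        d = exp.data
        assert np.allclose(
            d.loc[d.condition == "vehicle", "proportion"], expit(-0.5)
        )
        assert np.allclose(d.loc[d.condition == "drug", "proportion"], expit(-1.5))

    def test_effect_recovery_monte_carlo(self):
        """Mean recovered logit difference matches the planted -1.0."""
        diffs = []
        for s in range(3000):
            exp = sim.simulate_cga(
                sim.CgaSimConfig(drug_effects={"drug": -1.0}, seed=s)
            )
            d = exp.data
            diffs.append(
                logit(d.loc[d.condition == "drug", "proportion"]).mean()
                - logit(d.loc[d.condition == "vehicle", "proportion"]).mean()
            )
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-1.0, abs=4 * mc_se)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sim.CgaSimConfig(assay_sd=-0.1)
        with pytest.raises(ValueError):
            sim.CgaSimConfig(baseline_logit=np.inf)

    def test_seed_determinism(self):
        cfg = sim.CgaSimConfig(drug_effects={"d": -0.4}, seed=9)
        pd.testing.assert_frame_equal(
            sim.simulate_cga(cfg).data, sim.simulate_cga(cfg).data
        )


class TestCheckerboardSim:
    PX = FourPLParams(0.0, 1.0, 100.0, 1.3)
    PY = FourPLParams(0.0, 1.0, 5.0, 0.9)

    def test_5x9_grid_has_45_combinations(self):
        board = sim.simulate_checkerboard(
            [1, 2, 3, 4, 5], np.arange(1.0, 10.0), (self.PX, self.PY), seed=0
        )
        assert board.n_combinations == 45
        combos = board.data[(board.data.dose_x > 0) & (board.data.dose_y > 0)]
        assert combos.groupby(["dose_x", "dose_y"]).ngroups == 45

    def test_exact_bliss_null(self):
        board = sim.simulate_checkerboard(
            [10, 100], [1, 5, 25], (self.PX, self.PY), noise_sd=0.0, seed=0
        )
        d = board.data
        u = d.loc[(d.dose_x == 0) & (d.dose_y == 0), "response"].mean()
        for dx in board.doses_x:
            for dy in board.doses_y:
                vx = d.loc[(d.dose_x == dx) & (d.dose_y == 0), "response"].mean()
                vy = d.loc[(d.dose_y == dy) & (d.dose_x == 0), "response"].mean()
                combo = d.loc[(d.dose_x == dx) & (d.dose_y == dy), "response"].mean()
                assert combo == pytest.approx(vx * vy / u, abs=1e-12)

    def test_planted_bump_localized(self):
        board = sim.simulate_checkerboard(
            [10, 100], [1, 5, 25], (self.PX, self.PY),
            synergy_bump={(1, 2): 0.2}, noise_sd=0.0, seed=0,
        )
        d = board.data
        u = d.loc[(d.dose_x == 0) & (d.dose_y == 0), "response"].mean()
        for i, dx in enumerate(board.doses_x):
            for j, dy in enumerate(board.doses_y):
                vx = d.loc[(d.dose_x == dx) & (d.dose_y == 0), "response"].mean()
                vy = d.loc[(d.dose_y == dy) & (d.dose_x == 0), "response"].mean()
                combo = d.loc[(d.dose_x == dx) & (d.dose_y == dy), "response"].mean()
                dev = (vx * vy / u - combo) / u
                expected = 0.2 if (i, j) == (1, 2) else 0.0
                assert dev == pytest.approx(expected, abs=1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_checkerboard([1], [1], (self.PX, self.PY), noise_sd=-1)


class TestSmallGenerators:
    def test_doseresponse_noise_free_exact(self):
        p = FourPLParams(0.1, 1.0, 10.0, 1.5)
        doses = [0.1, 1, 10, 100]
        df = sim.simulate_doseresponse({"g": p}, doses, replicates=2, noise_cv=0)
        for _, row in df.iterrows():
            assert row.response == pytest.approx(four_pl(row.dose, *p))

    def test_blot_loading_control_identity(self):
        df = sim.simulate_blot(beta_load=1.0, noise_sd=0.0, seed=3)
        resid = np.log2(df.signal) - np.log2(df.loading)
        assert np.allclose(resid, resid.iloc[0])

    def test_foci_positive_fraction_vs_counting_oracle(self):
        thr = 5
        df = sim.simulate_foci(
            n_cells=10_000, positive_fraction=0.35, mu_positive=8.0,
            mu_background=0.5, seed=7,
        )
        empirical = (df.foci_count >= thr).mean()
        oracle = 0.35 * poisson.sf(thr - 1, 8.0) + 0.65 * poisson.sf(thr - 1, 0.5)
        se = np.sqrt(oracle * (1 - oracle) / len(df))
        assert empirical == pytest.approx(oracle, abs=4 * se)

    def test_foci_invalid_params(self):
        with pytest.raises(ValueError):
            sim.simulate_foci(10, positive_fraction=1.5, mu_positive=3)
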