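import numpy as np
import pandas as pd
import pytest

import sexseldiv as sd


class TestMatingAssays:
    def test_population_structure(self):
        truth = sd.SyntheticTruth()
        df = sd.simulate_mating_assays(truth, n_populations_per_line=4, lines_per_regime=3, seed=1)
        males = df[df["sex"] == "male"]
        females = df[df["sex"] == "female"]
        # one focal male per male-assay population, five females per female-assay population
        assert males.groupby("mating_population_id").size().eq(1).all()
        assert females.groupby("mating_population_id").size().eq(5).all()
        assert (males.groupby(["regime", "line_id"]).size() == 4).all()

    def test_regime_mating_means(self):
        """Female mating-count means track the regime rates (1.0 vs 2.1)."""
        truth = sd.SyntheticTruth()
        df = sd.simulate_mating_assays(
            truth, n_populations_per_line=40, lines_per_regime=4, seed=2,
            n_female_populations_per_line=40,
        )
        f = df[df["sex"] == "female"]
        for regime, rate in (("WSS", 1.0), ("SSS", 2.1)):
            x = f.loc[f["regime"] == regime, "matings"]
            se = x.std() / np.sqrt(len(x))
            assert abs(x.mean() - rate) < 3 * se + 1e-9

    def test_null_slope_yields_flat_regression(self):
        truth = sd.SyntheticTruth(bateman_slope_by_regime={"WSS": 0.0, "SSS": 0.0})
        df = sd.simulate_mating_assays(
            truth, n_populations_per_line=60, lines_per_regime=4, seed=3,
            n_female_populations_per_line=60,
        )
        f = df[(df["sex"] == "female") & (df["regime"] == "SSS")]
        kept, _ = sd.exclude_zero_success(f)
        slope, se = sd.bateman_gradient(kept)
        assert abs(slope) < 3 * se

    def test_zero_matings_implies_zero_offspring(self):
        truth = sd.SyntheticTruth()
        df = sd.simulate_mating_assays(truth, n_populations_per_line=20, seed=4)
        zero = df[df["matings"] == 0]
        assert (zero["offspring"] == 0).all()

    def test_determinism(self):
        truth = sd.SyntheticTruth()
        a = sd.simulate_mating_assays(truth, seed=9)
        b = sd.simulate_mating_assays(truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_mating_assays(sd.SyntheticTruth(), n_populations_per_line=0)


class TestDoubleMatings:
    def test_design_is_fully_crossed(self):
        truth = sd.SyntheticTruth()
        df = sd.simulate_double_matings(truth, lines_per_regime=4, n_females_per_cell=3, seed=1)
        for regime in ("WSS", "SSS"):
            cells = df[df["regime"] == regime].groupby(["female_line", "male_line"]).size()
            assert len(cells) == 16 and (cells == 3).all()

    def test_null_case_pooled_p2(self):
        """With no line effects, no interaction and no overdispersion, pooled
        hatched/eggs sits within 3 binomial SEs of the baseline."""
        truth = sd.SyntheticTruth(
            interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.0},
            line_effect_sd=0.0,
            overdispersion_rho=0.0,
            baseline_p2_by_regime={"WSS": 0.5, "SSS": 0.5},
        )
        df = sd.simulate_double_matings(truth, lines_per_regime=2, n_females_per_cell=2500, seed=6)
        w = df[df["regime"] == "WSS"]
        n_eggs = w["eggs_total"].sum()
        p_hat = w["hatched"].sum() / n_eggs
        assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / n_eggs)

    def test_regime_baselines_order(self):
        truth = sd.SyntheticTruth(
            interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.0}, line_effect_sd=0.0,
            overdispersion_rho=0.0,
        )
        df = sd.simulate_double_matings(truth, lines_per_regime=2, n_females_per_cell=2000, seed=7)
        means = df.assign(p2=df["hatched"] / df["eggs_total"]).groupby("regime")["p2"].mean()
        assert means["WSS"] == pytest.approx(0.44, abs=0.02)
        assert means["SSS"] == pytest.approx(0.61, abs=0.02)

    def test_beta_binomial_variance_oracle(self):
        """With fixed egg count m the hatched-count variance matches
        m p (1-p) (1 + (m-1) rho); rho > 0 strictly inflates the P2 spread."""
        m, p = 40, 0.5
        base = dict(
            interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.0},
            line_effect_sd=0.0,
            baseline_p2_by_regime={"WSS": p, "SSS": p},
        )
        out = {}
        for rho in (0.0, 0.3):
            truth = sd.SyntheticTruth(overdispersion_rho=rho, **base)
            df = sd.simulate_double_matings(
                truth, lines_per_regime=2, n_females_per_cell=2500,
                eggs_per_female=m, seed=8,
            )
            w = df[df["regime"] == "WSS"]
            out[rho] = w["hatched"].var(ddof=1)
        for rho in (0.0, 0.3):
            expected = m * p * (1 - p) * (1 + (m - 1) * rho)
            assert out[rho] == pytest.approx(expected, rel=0.1)
        assert out[0.3] > out[0.0]

    def test_determinism_and_validator_compatibility(self, tmp_path):
        truth = sd.SyntheticTruth()
        a = sd.simulate_double_matings(truth, seed=3)
        b = sd.simulate_double_matings(truth, seed=3)
        pd.testing.assert_frame_equal(a, b)
        from sexseldiv import io as sio

        sio.write_table(a, tmp_path / "d.csv")
        back = sio.read_double_matings(tmp_path / "d.csv")
        pd.testing.assert_frame_equal(back, a)

    def test_invalid_egg_spec_rejected(self):
        with pytest.raises(ValueError, match="distribution spec"):
            sd.simulate_double_matings(sd.SyntheticTruth(), eggs_per_female="lots", seed=1)


class TestExpression:
    def test_equal_sds_give_unit_median_ratio(self):
        truth = sd.SyntheticTruth()
        data, _, _ = sd.simulate_expression(truth, n_genes=8000, seed=10)
        tab = sd.divergence_table(data, "female")
        assert np.nanmedian(tab["ratio"]) == pytest.approx(1.0, abs=0.05)

    def test_sd_ratio_drives_set_median_ratio(self):
        """A set with SSS:WSS replicate-SD ratio 1.5 shows a median divergence
        ratio near 1.5 while the background stays near 1 (the mean absolute
        deviation of a normal is proportional to sigma)."""
        truth = sd.SyntheticTruth()
        truth.replicate_sd_by_regime_and_geneset = {
            "background": {"WSS": 0.3, "SSS": 0.3},
            "SFP": {"WSS": 0.3, "SSS": 0.45},
        }
        data, sets, _ = sd.simulate_expression(
            truth, n_genes=6000, geneset_spec={"SFP": 300}, seed=11
        )
        tab = sd.divergence_table(data, "male")
        set_med = np.nanmedian(tab.loc[tab.index.intersection(sets["SFP"]), "ratio"])
        bg_med = np.nanmedian(tab.drop(index=sets["SFP"])["ratio"])
        assert set_med == pytest.approx(1.5, rel=0.08)
        assert bg_med == pytest.approx(1.0, abs=0.05)

    def test_sample_grid_and_determinism(self):
        truth = sd.SyntheticTruth()
        a, _, _ = sd.simulate_expression(truth, n_genes=100, seed=12)
        b, _, _ = sd.simulate_expression(truth, n_genes=100, seed=12)
        pd.testing.assert_frame_equal(a.values, b.values)
        combos = a.sample_meta.groupby(["sex", "regime"]).size()
        assert (combos == 4).all() and len(combos) == 4

    def test_overlapping_sets_rejected(self):
        truth = sd.SyntheticTruth()
        truth.replicate_sd_by_regime_and_geneset["X"] = {"WSS": 0.3, "SSS": 0.3}
        with pytest.raises(ValueError, match="overlap"):
            sd.simulate_expression(
                truth, n_genes=100, geneset_spec={"SFP": [0, 1, 2], "X": [2, 3]}, seed=1
            )

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            sd.simulate_expression(sd.SyntheticTruth(), n_genes=10, geneset_spec={"SFP": [11]}, seed=1)


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        truth = sd.SyntheticTruth()
        truth.to_json(tmp_path / "truth.json")
        back = sd.SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == truth

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mating_rate_by_regime": {"WSS": 0.0, "SSS": 2.0}},
            {"overdispersion_rho": 1.0},
            {"baseline_p2_by_regime": {"WSS": 0.0, "SSS": 0.5}},
            {"line_effect_sd": -1.0},
        ],
    )
    def test_invalid_truth_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SyntheticTruth(**kwargs)
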