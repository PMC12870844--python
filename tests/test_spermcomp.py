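import numpy as np
import pandas as pd
import patsy
import pytest
from scipy import stats

import sexseldiv as sd
from sexseldiv.spermcomp import _safe_bartlett, _weighted_reml_nll


def _dm(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "female_id", "regime", "female_line", "male_line",
            "eggs_total", "hatched", "first_mating_ok", "second_mating_ok",
        ],
    )


class TestFilterAndP2:
    def test_exclusion_rules(self):
        df = _dm(
            [
                ("f1", "WSS", "A", "B", 40, 0, True, True),    # P2 = 0: no competition shown
                ("f2", "WSS", "A", "B", 40, 22, True, False),  # missed second mating
                ("f3", "WSS", "A", "B", 40, 22, False, True),  # missed first mating
                ("f4", "WSS", "A", "B", 0, 0, True, True),     # laid no eggs
                ("f5", "WSS", "A", "B", 40, 22, True, True),   # competed
            ]
        )
        kept = sd.filter_competing_females(df)
        assert list(kept["female_id"]) == ["f5"]

    @pytest.mark.parametrize("hatched, eggs, want", [(20, 40, 0.5), (40, 40, 1.0), (1, 3, 1 / 3)])
    def test_p2_values(self, hatched, eggs, want):
        df = _dm([("f", "WSS", "A", "B", eggs, hatched, True, True)])
        assert sd.compute_p2(df).iloc[0] == pytest.approx(want)

    def test_arcsine_transform_closed_form(self):
        assert sd.arcsine_sqrt(0.25) == pytest.approx(np.pi / 6)


def _irls_quasibinomial(y, m, X, tol=1e-12, maxit=200):
    """Independent oracle: textbook IRLS for the binomial-denominator logit
    GLM, returning the deviance."""
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    eta = np.full(y.size, np.log((y.sum() + 0.5) / (m.sum() - y.sum() + 0.5)))
    for _ in range(maxit):
        mu = 1 / (1 + np.exp(-eta))
        w = m * mu * (1 - mu)
        z = eta + (y - m * mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        eta_new = X @ beta_new
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        beta, eta = beta_new, eta_new
    mu = 1 / (1 + np.exp(-eta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (m * mu)), 0.0)
        t2 = np.where(m - y > 0, (m - y) * np.log((m - y) / (m - m * mu)), 0.0)
    return 2.0 * np.sum(t1 + t2)


class TestCrossedGlm:
    def test_null_data_gives_zero_term_deviances(self):
        rows = []
        for ml in ("A", "B"):
            for fl in ("A", "B"):
                for h, e in [(20, 40), (10, 40)]:
                    rows.append((f"{ml}{fl}{h}", "WSS", fl, ml, e, h, True, True))
        res = sd.fit_crossed_glm(_dm(rows))
        terms = res.deviance_table.set_index("term")
        for t in ("male_line (line)", "female_line (line)", "male x female"):
            assert terms.loc[t, "deviance"] == pytest.approx(0.0, abs=1e-8)
            assert terms.loc[t, "F"] == pytest.approx(0.0, abs=1e-8)

    def test_deviance_table_matches_independent_irls_oracle(self):
        truth = sd.SyntheticTruth()
        rec = sd.filter_competing_females(sd.simulate_double_matings(truth, seed=17))
        rec = rec[rec["regime"] == "SSS"]
        res = sd.fit_crossed_glm(rec)
        y = rec["hatched"].to_numpy(float)
        m = rec["eggs_total"].to_numpy(float)
        devs = []
        for rhs in ["1", "C(male_line)", "C(male_line) + C(female_line)",
                    "C(male_line) * C(female_line)"]:
            X = patsy.dmatrix(rhs, rec)
            devs.append(_irls_quasibinomial(y, m, X))
        expected = [devs[0] - devs[1], devs[1] - devs[2], devs[2] - devs[3], devs[3]]
        np.testing.assert_allclose(res.deviance_table["deviance"].to_numpy(), expected, atol=1e-6)

    def test_interaction_df_and_additivity(self, double_mating_frame):
        rec = double_mating_frame[double_mating_frame["regime"] == "WSS"]
        res = sd.fit_crossed_glm(rec)
        terms = res.deviance_table.set_index("term")
        assert terms.loc["male x female", "df"] == 1  # (2-1)(2-1)
        # term deviances + residual deviance recover the null deviance
        y = rec["hatched"].to_numpy(float)
        m = rec["eggs_total"].to_numpy(float)
        null_dev = _irls_quasibinomial(y, m, np.ones((len(rec), 1)))
        assert res.deviance_table["deviance"].sum() == pytest.approx(null_dev, rel=1e-6)

    def test_predicted_mean_within_cell_range(self):
        truth = sd.SyntheticTruth()
        rec = sd.filter_competing_females(sd.simulate_double_matings(truth, seed=23))
        rec = rec[rec["regime"] == "WSS"]
        res = sd.fit_crossed_glm(rec)
        cell_p2 = rec.assign(p2=sd.compute_p2(rec)).groupby(["male_line", "female_line"])["p2"].mean()
        assert cell_p2.min() - 1e-9 <= res.predicted_mean_p2 <= cell_p2.max() + 1e-9

    def test_empty_cell_is_named(self):
        df = _dm(
            [
                ("f1", "WSS", "A", "A", 40, 20, True, True),
                ("f2", "WSS", "B", "A", 40, 20, True, True),
                ("f3", "WSS", "A", "B", 40, 20, True, True),
            ]
        )
        with pytest.raises(ValueError, match="empty design cell"):
            sd.fit_crossed_glm(df)


class TestInteractionVarianceComponent:
    def test_deterministic_across_runs(self):
        truth = sd.SyntheticTruth()
        rec = sd.filter_competing_females(sd.simulate_double_matings(truth, seed=31))
        rec = rec[rec["regime"] == "SSS"]
        assert sd.interaction_variance_component(rec) == sd.interaction_variance_component(rec)

    def test_null_interaction_estimates_near_boundary(self):
        truth = sd.SyntheticTruth(
            interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.0},
            line_effect_sd=0.0,
            overdispersion_rho=0.0,
            baseline_p2_by_regime={"WSS": 0.5, "SSS": 0.5},
        )
        ests = []
        for rep in range(12):
            rec = sd.filter_competing_females(
                sd.simulate_double_matings(truth, lines_per_regime=4, n_females_per_cell=7, seed=400 + rep)
            )
            v, _ = sd.interaction_variance_component(rec[rec["regime"] == "WSS"])
            ests.append(v)
        assert np.median(ests) < 0.05

    def test_moments_fallback_recovers_under_overdispersion(self):
        """Under beta-binomial overdispersion the moments estimator on cell
        logits stays close to the generating interaction variance (PQL-type
        estimators attenuate in this regime)."""
        truth = sd.SyntheticTruth()  # interaction var 0.633 in SSS, rho 0.15
        ests = []
        for rep in range(30):
            rec = sd.filter_competing_females(sd.simulate_double_matings(truth, seed=2200 + rep))
            v, se = sd.interaction_variance_component_moments(rec[rec["regime"] == "SSS"])
            ests.append(v)
            assert se > 0
        assert np.mean(ests) == pytest.approx(0.633, rel=0.25)

    def test_inner_weighted_reml_agrees_with_statsmodels_mixedlm(self):
        """With unit weights and the residual variance fixed at the MixedLM
        REML scale, minimizing the hand-rolled restricted likelihood over the
        crossed variance components must land on MixedLM's estimates."""
        import statsmodels.api as sm
        from scipy import optimize

        rng = np.random.default_rng(6)
        levels = 5
        male = rng.integers(0, levels, 150)
        female = rng.integers(0, levels, 150)
        y = (
            1.0
            + rng.normal(0, 0.7, levels)[male]
            + rng.normal(0, 0.5, levels)[female]
            + rng.normal(0, 0.4, 150)
        )
        df = pd.DataFrame({"y": y, "m": male.astype(str), "f": female.astype(str)})
        df["g"] = 1
        model = sm.MixedLM.from_formula(
            "y ~ 1", groups="g", vc_formula={"m": "0 + C(m)", "f": "0 + C(f)"}, data=df
        )
        ref = model.fit(reml=True)
        Zm = pd.get_dummies(df["m"]).to_numpy(float)
        Zf = pd.get_dummies(df["f"]).to_numpy(float)
        X = np.ones((150, 1))
        w = np.ones(150)
        res = optimize.minimize(
            lambda s: _weighted_reml_nll(s, y, X, [Zm, Zf], w, float(ref.scale)),
            np.array([0.3, 0.3]),
            method="L-BFGS-B",
            bounds=[(0.0, 10.0)] * 2,
        )
        # MixedLM orders vc components by formula key; compare as sorted pairs
        np.testing.assert_allclose(np.sort(res.x), np.sort(ref.vcomp), rtol=1e-3, atol=1e-4)


class TestLmmShareAndRatio:
    def test_self_comparison_is_null(self, double_mating_frame):
        rec = double_mating_frame[double_mating_frame["regime"] == "WSS"]
        out = sd.lmm_share_and_ratio_test(rec, rec)
        assert out.f_ratio == pytest.approx(1.0)
        assert out.p_one_sided == pytest.approx(0.5)
        assert out.share_by_regime["WSS"] == out.share_by_regime["SSS"]

    def test_detects_strong_sss_interaction(self):
        """Power check at the design scale: with interaction SD 0.8 vs 0 the
        one-sided ratio test should reject most of the time."""
        rejections = 0
        n_rep = 25
        for rep in range(n_rep):
            truth = sd.SyntheticTruth(
                interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.8},
                line_effect_sd=0.0,
                overdispersion_rho=0.0,
                baseline_p2_by_regime={"WSS": 0.5, "SSS": 0.5},
            )
            rec = sd.filter_competing_females(
                sd.simulate_double_matings(truth, n_females_per_cell=7, seed=900 + rep)
            )
            out = sd.lmm_share_and_ratio_test(
                rec[rec["regime"] == "WSS"], rec[rec["regime"] == "SSS"]
            )
            rejections += out.p_one_sided < 0.05
        assert rejections / n_rep > 0.8


class TestResidualBootstrap:
    def test_bartlett_degenerate_groups(self):
        chi2, df, p = _safe_bartlett([np.array([1.0, 1.0, 1.0]), np.array([2.0, 2.0, 2.0])])
        assert chi2 == 0.0 and p == 1.0

    def test_null_ratio_near_one(self):
        truth = sd.SyntheticTruth(
            interaction_sd_by_regime={"WSS": 0.0, "SSS": 0.0},
            line_effect_sd=0.0,
            overdispersion_rho=0.0,
            baseline_p2_by_regime={"WSS": 0.5, "SSS": 0.5},
        )
        fs = []
        for rep in range(10):
            rec = sd.filter_competing_females(sd.simulate_double_matings(truth, seed=1300 + rep))
            by = {r: rec[rec["regime"] == r] for r in ("WSS", "SSS")}
            out = sd.residual_cell_bootstrap(by, n_boot=150, rng=np.random.default_rng(rep))
            fs.append(out.f_ratio)
        assert 0.5 < np.median(fs) < 2.0

    def test_bca_intervals_well_formed(self, double_mating_frame):
        by = {r: double_mating_frame[double_mating_frame["regime"] == r] for r in ("WSS", "SSS")}
        out = sd.residual_cell_bootstrap(by, n_boot=400, rng=np.random.default_rng(5))
        for regime in ("WSS", "SSS"):
            lo, hi = out.ci_by_regime[regime]
            assert lo <= hi
            assert out.variance_by_regime[regime] >= 0


class TestWithinVsBetween:
    def test_identical_groups_give_no_evidence(self):
        # within and between hold the same values, so the one-sided p can
        # never drop below its null-center value of one half
        rows = []
        for i, (fl, ml) in enumerate([("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")] * 3):
            rows.append((f"f{i}", "WSS", fl, ml, 40, 20, True, True))
        out = sd.within_vs_between_comparison({"WSS": _dm(rows)})
        assert out["WSS"] >= 0.5

    def test_smallest_exact_p_for_three_vs_three(self):
        rows = [
            ("w1", "WSS", "A", "A", 10, 9, True, True),
            ("w2", "WSS", "B", "B", 10, 9, True, True),
            ("w3", "WSS", "C", "C", 10, 9, True, True),
            ("b1", "WSS", "A", "B", 10, 1, True, True),
            ("b2", "WSS", "B", "C", 10, 1, True, True),
            ("b3", "WSS", "C", "A", 10, 1, True, True),
        ]
        out = sd.within_vs_between_comparison({"WSS": _dm(rows)})
        assert out["WSS"] == pytest.approx(0.05)  # 1 of C(6,3)=20 arrangements

    def test_one_group_empty_rejected(self):
        rows = [("f1", "WSS", "A", "B", 10, 5, True, True)]
        with pytest.raises(ValueError):
            sd.within_vs_between_comparison({"WSS": _dm(rows)})
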