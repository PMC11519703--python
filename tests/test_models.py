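"""Model layer: quasibinomial IRLS, per-bin contrast engine, mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import deltagaze as dg
from deltagaze.models import (BinwiseGazeModel, QuasibinomialGLM,
                              binwise_contrasts, effect_size_d,
                              marginal_contrast, significant_windows)


def _random_proportion_fixture(seed=0, n=150):
    rng = np.random.default_rng(seed)
    d = pd.DataFrame({
        "n": rng.integers(1, 30, n).astype(float),
        "g": rng.choice(["a", "b"], n),
        "b": rng.integers(0, 5, n),
    })
    p = 0.3 + 0.1 * (d["g"] == "b") + 0.05 * d["b"]
    d["proportion"] = rng.binomial(d["n"].astype(int), p) / d["n"]
    return d


class TestQuasibinomialGLM:
    def test_saturated_two_cell_identity(self):
        """Equal-weight cells at 0.5 and 0.8: intercept 0, slope ln 4."""
        df = pd.DataFrame({"proportion": [0.5, 0.8], "x": [0, 1],
                           "n": [10, 10]})
        m = QuasibinomialGLM("proportion ~ x").fit(df)
        assert abs(m.params_.iloc[0]) < 1e-10
        assert abs(m.params_.iloc[1] - np.log(4)) < 1e-10

    def test_matches_brute_force_likelihood_maximizer(self):
        """IRLS point estimates equal direct numerical maximization of the
        weighted binomial log-likelihood (independent optimizer)."""
        d = _random_proportion_fixture()
        m = QuasibinomialGLM("proportion ~ C(b) * g").fit(d)

        from patsy import dmatrices
        ymat, X = dmatrices("proportion ~ C(b) * g", d,
                            return_type="dataframe")
        Xv, yv = X.to_numpy(), ymat.to_numpy().ravel()
        w = d["n"].to_numpy(float)

        def nll(beta):
            mu = np.clip(expit(Xv @ beta), 1e-12, 1 - 1e-12)
            return -np.sum(w * (yv * np.log(mu) + (1 - yv) * np.log(1 - mu)))

        def grad(beta):
            mu = expit(Xv @ beta)
            return -Xv.T @ (w * (yv - mu))

        res = minimize(nll, np.zeros(Xv.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        assert np.max(np.abs(m.params_.to_numpy() - res.x)) < 1e-6

    def test_point_estimates_agree_with_statsmodels(self):
        """Dispersion scaling touches only the SEs: point estimates equal a
        plain binomial GLM's."""
        import statsmodels.api as sm
        d = _random_proportion_fixture(seed=3)
        m = QuasibinomialGLM("proportion ~ C(b) * g").fit(d)
        ref = sm.GLM.from_formula("proportion ~ C(b) * g", d,
                                  family=sm.families.Binomial(),
                                  freq_weights=d["n"]).fit()
        assert np.allclose(m.params_.to_numpy(), ref.params.to_numpy(),
                           atol=1e-8)

    def test_se_is_sqrt_dispersion_times_binomial_se(self):
        d = _random_proportion_fixture(seed=4)
        m = QuasibinomialGLM("proportion ~ g").fit(d)
        unit_cov = m.cov_params_ / m.dispersion_
        assert np.allclose(m.bse_.to_numpy(),
                           np.sqrt(np.diag(unit_cov) * m.dispersion_))
        assert m.dispersion_ > 0

    def test_constant_proportions_give_zero_slopes(self):
        df = pd.DataFrame({"proportion": [0.6] * 8, "x": [0, 1] * 4,
                           "n": [5.0] * 8})
        m = QuasibinomialGLM("proportion ~ x").fit(df)
        assert abs(m.params_.iloc[1]) < 1e-9
        assert m.dispersion_ < 1e-12

    def test_response_out_of_range_rejected(self):
        df = pd.DataFrame({"proportion": [0.5, 1.2], "x": [0, 1],
                           "n": [5.0, 5.0]})
        with pytest.raises(ValueError, match="proportion"):
            QuasibinomialGLM("proportion ~ x").fit(df)


class TestBinwiseEngine:
    def _cells(self, seed=0, n_bins=12, effect=None):
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(n_bins):
            for g in ("control", "pwa"):
                for unit in range(25):
                    p = 0.6 if g == "control" else 0.6 + (
                        effect(b) if effect else 0.0)
                    n = int(rng.integers(2, 12))
                    rows.append((b, g, n, rng.binomial(n, p) / n))
        return pd.DataFrame(rows, columns=["bin", "group", "n", "proportion"])

    def test_single_bin_contrast_equals_glm_coefficient(self):
        """On one bin the engine's contrast is exactly the treatment-coded
        group coefficient of the formula route."""
        cells = self._cells(n_bins=1)
        bw = BinwiseGazeModel(factors=("group",)).fit(cells)
        contr = binwise_contrasts(bw, "group", "pwa", "control")
        ref = QuasibinomialGLM("proportion ~ C(group)").fit(cells)
        assert contr.loc[0, "estimate"] == pytest.approx(
            ref.params_["C(group)[T.pwa]"], abs=1e-10)

    def test_cell_logits_are_weighted_mean_logits(self):
        cells = self._cells()
        bw = BinwiseGazeModel(factors=("group",)).fit(cells)
        one = cells[(cells["bin"] == 3) & (cells["group"] == "pwa")]
        p = (one["proportion"] * one["n"]).sum() / one["n"].sum()
        got = bw.cells_.query("bin == 3 and group == 'pwa'")["eta"].iloc[0]
        assert got == pytest.approx(logit(p), abs=1e-12)

    def test_detects_localized_group_effect(self):
        cells = self._cells(seed=1,
                            effect=lambda b: -0.25 if 4 <= b <= 7 else 0.0)
        bw = BinwiseGazeModel(factors=("group",)).fit(cells)
        contr = binwise_contrasts(bw, "group", "pwa", "control")
        hot = contr[(contr["bin"] >= 4) & (contr["bin"] <= 7)]
        assert (hot["estimate"] < 0).all() and hot["significant"].all()

    def test_marginal_contrast_is_weighted_mean_of_bins(self):
        cells = self._cells(seed=2)
        bw = BinwiseGazeModel(factors=("group",)).fit(cells)
        contr = binwise_contrasts(bw, "group", "pwa", "control")
        w = bw.cells_.groupby("bin")["weight"].sum().reindex(contr["bin"])
        got = marginal_contrast(contr, w.to_numpy())
        expect = np.average(contr["estimate"], weights=w)
        assert got == pytest.approx(expect)

    def test_missing_level_raises(self):
        cells = self._cells()
        bw = BinwiseGazeModel(factors=("group",)).fit(cells)
        with pytest.raises(KeyError, match="not estimable"):
            binwise_contrasts(bw, "group", "nosuch", "control")

    def test_interaction_contrast_difference_of_differences(self):
        rng = np.random.default_rng(5)
        rows = []
        probs = {("control", "lab"): 0.7, ("pwa", "lab"): 0.6,
                 ("control", "web"): 0.7, ("pwa", "web"): 0.45}
        for b in range(6):
            for (g, m), p in probs.items():
                for _ in range(40):
                    n = int(rng.integers(3, 12))
                    rows.append((b, g, m, n, rng.binomial(n, p) / n))
        cells = pd.DataFrame(rows, columns=["bin", "group", "modality",
                                            "n", "proportion"])
        bw = BinwiseGazeModel(factors=("group", "modality")).fit(cells)
        contr = binwise_contrasts(bw, "group", "pwa", "control",
                                  interaction_with=("modality", "web", "lab"))
        # group deficit larger on the web -> negative interaction
        assert (contr["estimate"] < 0).all()


def test_significant_windows_segments_runs_and_signs():
    contr = pd.DataFrame({
        "bin": range(10),
        "estimate": [1, 1, 1, -1, -1, 1, 1, 1, 1, 1],
        "significant": [False, True, True, True, True,
                        False, True, True, False, True],
    })
    win = significant_windows(contr)
    assert win.values.tolist() == [[1, 2, 1], [3, 4, -1],
                                   [6, 7, 1], [9, 9, 1]]


def test_effect_size_matches_t_df_relation():
    assert effect_size_d(4.269, 65) == pytest.approx(1.058, abs=5e-3)
    assert effect_size_d(-4.913, 2275) == pytest.approx(-0.206, abs=5e-3)


class TestAccuracyModel:
    def test_saturated_two_by_two_matches_log_odds(self):
        """Fixed-effects logistic on a saturated design reproduces the
        closed-form cell log-odds differences."""
        cellp = {("active", "lab"): 0.8, ("passive", "lab"): 0.6,
                 ("active", "web"): 0.7, ("passive", "web"): 0.5}
        rows = []
        for (s, m), p in cellp.items():
            k = int(round(p * 20))
            rows += [(s, m, True)] * k + [(s, m, False)] * (20 - k)
        df = pd.DataFrame(rows, columns=["structure", "modality", "accurate"])
        df["participant"] = "p1"
        df["trial_id"] = [f"t{i}" for i in range(len(df))]
        fit = dg.fit_accuracy(df, random_effects=False)
        lo = {k: logit(v) for k, v in cellp.items()}
        assert fit.coef("Intercept").estimate == pytest.approx(
            lo[("active", "lab")], abs=1e-6)
        assert fit.coef("C(structure)[T.passive]").estimate == pytest.approx(
            lo[("passive", "lab")] - lo[("active", "lab")], abs=1e-6)
        inter = (lo[("passive", "web")] - lo[("active", "web")]
                 - lo[("passive", "lab")] + lo[("active", "lab")])
        assert fit.coef(
            "C(structure)[T.passive]:C(modality)[T.web]"
        ).estimate == pytest.approx(inter, abs=1e-6)

    def test_degenerate_response_rejected(self):
        df = pd.DataFrame({"structure": ["active"] * 4,
                           "modality": ["lab"] * 4,
                           "accurate": [True] * 4,
                           "participant": "p1",
                           "trial_id": list("abcd")})
        with pytest.raises(ValueError, match="degenerate"):
            dg.fit_accuracy(df)

    def test_recovers_passive_deficit_with_random_effects(self):
        cfg = dg.SimulationConfig(seed=3)
        trials, _ = dg.simulate_study(cfg, return_gaze=False)
        pwa = trials[(trials["group"] == "pwa")
                     & (trials["structure"] != "filler")]
        fit = dg.fit_accuracy(pwa)
        row = fit.coef("C(structure)[T.passive]")
        assert row.estimate < 0 and row.p < 0.05


class TestRTModel:
    def test_two_condition_ols_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "group": "pwa", "structure": "active",
            "modality": ["lab"] * 30 + ["web"] * 30,
            "participant": "p1",
            "trial_id": [f"t{i}" for i in range(60)],
            "sqrt_rt": np.r_[rng.normal(70, 3, 30), rng.normal(55, 3, 30)],
        })
        fit = dg.fit_rt(df, random_effects=False)
        means = df.groupby("modality")["sqrt_rt"].mean()
        assert fit.coef("C(modality)[T.web]").estimate == pytest.approx(
            means["web"] - means["lab"], abs=1e-9)

    def test_mixed_fit_recovers_injected_web_shift(self):
        """A -40 shift on the sqrt scale for the web session is recovered
        by the modality coefficient."""
        rng = np.random.default_rng(1)
        rows = []
        for p in range(16):
            u = rng.normal(0, 4)
            for m, shift in (("lab", 0.0), ("web", -40.0)):
                for t in range(30):
                    rows.append((f"p{p}", "pwa", "active", m, f"t{t}",
                                 70 + u + shift + rng.normal(0, 5)))
        df = pd.DataFrame(rows, columns=["participant", "group", "structure",
                                         "modality", "trial_id", "sqrt_rt"])
        fit = dg.fit_rt(df)
        est = fit.coef("C(modality)[T.web]").estimate
        assert est == pytest.approx(-40.0, abs=3.0)
        assert 0 <= fit.extra["r2_marginal"] <= fit.extra["r2_conditional"] <= 1

    def test_null_simulation_covers_zero(self):
        from conftest import null_config
        trials, _ = dg.simulate_study(null_config(17, n_per_group=8),
                                      return_gaze=False,
                                      structures=("active", "passive",
                                                  "locative"))
        df = dg.transform_rt(trials)
        fit = dg.fit_rt(df, random_effects=False)
        row = fit.coef("C(group)[T.pwa]")
        assert row.ci_low < 0 < row.ci_high
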