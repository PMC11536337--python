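import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from peepkit.mixed import (descriptive_means, emm_pairwise_tukey,
                           fit_logistic_glmm, fit_lmm, glmm_marginal_loglik,
                           reml_variance_components)
from peepkit.synth import (PARAMS, PopulationSpec, simulate_call_table,
                           simulate_nights)


def _one_way_data(rng, k=8, n=12, sigma_b=2.0, sigma_e=1.0, mu=10.0):
    b = rng.normal(0, sigma_b, size=k)
    y = (mu + np.repeat(b, n) + rng.normal(0, sigma_e, size=k * n))
    groups = np.repeat([f"g{i}" for i in range(k)], n)
    return y, groups


class TestREMLCore:
    def test_zero_between_variance_equals_ols(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([2.0, 0.5]) + rng.normal(0, 1.0, n)
        groups = np.repeat(["a", "b", "c"], 20)
        rng.shuffle(groups)
        fit = reml_variance_components(y, X, {"g": groups})
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # no true group structure: REML collapses to (nearly) OLS
        assert fit.estimates == pytest.approx(ols, abs=0.02)

    def test_balanced_one_way_matches_anova_ems_oracle(self, rng):
        # balanced design: REML variance components equal the classical
        # expected-mean-squares estimators
        k, n = 10, 8
        y, groups = _one_way_data(rng, k=k, n=n)
        fit = reml_variance_components(y, np.ones((k * n, 1)), {"g": groups})
        df = pd.DataFrame({"y": y, "g": groups})
        means = df.groupby("g")["y"].mean()
        grand = df["y"].mean()
        msb = n * ((means - grand) ** 2).sum() / (k - 1)
        msw = ((df["y"] - df["g"].map(means)) ** 2).sum() / (k * (n - 1))
        assert fit.random_variances["residual"] == pytest.approx(msw, rel=1e-4)
        assert fit.random_variances["g"] == pytest.approx((msb - msw) / n,
                                                          rel=1e-3)

    def test_against_statsmodels_mixedlm(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        y, groups = _one_way_data(rng, k=6, n=10)
        x = rng.normal(size=y.size)
        y = y + 0.7 * x
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        fit = reml_variance_components(
            y, np.column_stack([np.ones(y.size), x]), {"g": groups},
            names=["intercept", "x"])
        ref = smf.mixedlm("y ~ x", df, groups="g").fit(reml=True)
        assert fit.estimates == pytest.approx(
            [ref.params["Intercept"], ref.params["x"]], abs=1e-4)
        assert fit.random_variances["g"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3)

    def test_boundary_flagged_when_variance_collapses(self, rng):
        y = rng.normal(size=40)
        groups = np.repeat(["a", "b"], 20)
        fit = reml_variance_components(y, np.ones((40, 1)), {"g": groups})
        # two groups with no real difference: ratio usually hits the floor
        assert fit.random_variances["g"] >= 0.0
        assert isinstance(fit.boundary, bool)


def _condition_table(seed, n_males=12, calls=25):
    spec = PopulationSpec(n_males=n_males, seed=seed)
    spec = dataclasses.replace(
        spec, recording_cv={p: 0.0 for p in PARAMS})
    return simulate_call_table(spec, 3, calls)


class TestLMM:
    def test_wald_terms_and_reference_coding(self):
        tab = _condition_table(70)
        fit = fit_lmm(tab, "cd_s")
        assert fit.extra["condition_levels"][0] == "brooding"
        terms = fit.extra["wald_terms"].set_index("term")
        assert terms.loc["condition", "df"] == 2
        assert terms.loc["condition", "p"] < 0.001

    def test_contrast_linearity(self):
        tab = _condition_table(71)
        cc = emm_pairwise_tukey(fit_lmm(tab, "cd_s"))
        cc = cc.set_index("contrast")["estimate"]
        ab = cc["Brooding vs. Guarding"]
        ac = cc["Brooding vs. No clutches"]
        bc = cc["Guarding vs. No clutches"]
        assert ab == pytest.approx(ac - bc, abs=1e-12)

    def test_identical_groups_give_null_contrasts(self, rng):
        n = 300
        tab = pd.DataFrame({
            "male_id": np.repeat([f"m{i}" for i in range(10)], 30),
            "condition": np.tile(["brooding", "guarding", "no clutches"], 100),
            "cd_s": 0.064 + rng.normal(0, 0.005, n),
            "temperature_c": 25.0 + rng.normal(0, 1, n),
            "rainfall": rng.integers(0, 2, n),
        })
        cc = emm_pairwise_tukey(fit_lmm(tab, "cd_s"))
        assert np.all(np.abs(cc["estimate"]) < 0.003)
        assert np.all(cc["p_tukey"] > 0.05)

    def test_table4_contrast_recovery(self):
        tab = _condition_table(72, n_males=20, calls=30)
        cc = emm_pairwise_tukey(fit_lmm(tab, "cd_s")).set_index("contrast")
        bg = cc.loc["Brooding vs. Guarding"]
        assert bg["estimate"] == pytest.approx(-0.005, abs=2.5 * bg["se"])
        cc_i = emm_pairwise_tukey(fit_lmm(tab, "ici_s")).set_index("contrast")
        assert cc_i.loc["Brooding vs. Guarding", "estimate"] > 0

    def test_temperature_slope_recovered(self):
        tab = _condition_table(73, n_males=20, calls=30)
        fit = fit_lmm(tab, "cd_s")
        j = fit.names.index("temperature_c")
        assert fit.estimates[j] == pytest.approx(-0.0005, abs=3 * fit.se[j])


class TestDescriptiveMeans:
    def test_zero_variance_balanced_equals_grand_mean(self, rng):
        y = rng.normal(10.0, 1.0, size=90)
        tab = pd.DataFrame({
            "male_id": np.repeat(["a", "b", "c"], 30),
            "recording_id": np.repeat([f"r{i}" for i in range(9)], 10),
            "condition": "no clutches", "y": y})
        with pytest.warns(UserWarning, match="degenerate"):
            fit = descriptive_means(tab, "y")
        assert fit.estimates[0] == pytest.approx(y.mean(), abs=0.05)

    def test_population_cd_mean_recovered(self):
        tab = simulate_call_table(PopulationSpec(n_males=20, seed=74), 3, 30)
        fit = descriptive_means(tab, "cd_s")
        assert fit.estimates[0] == pytest.approx(0.064, abs=3 * fit.se[0] + 1e-3)

    def test_unbalanced_toy_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(7)
        rows = []
        for m in range(5):
            bm = rng.normal(0, 1.0)
            for r in range(3 if m % 2 == 0 else 4):
                br = rng.normal(0, 0.7)
                for _ in range(rng.integers(6, 12)):
                    rows.append({"male_id": f"m{m}",
                                 "recording_id": f"m{m}r{r}",
                                 "condition": "guarding",
                                 "y": 5.0 + bm + br + rng.normal(0, 0.8)})
        df = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = descriptive_means(df, "y")
        ref = smf.mixedlm("y ~ 1", df, groups="male_id",
                          re_formula="1",
                          vc_formula={"recording_id": "0 + C(recording_id)"}
                          ).fit(reml=True)
        assert fit.estimates[0] == pytest.approx(ref.params["Intercept"],
                                                 abs=1e-4)
        assert fit.random_variances["male_id"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), abs=1e-3)


def _glmm_nll_grid_oracle(df, beta, sigma):
    """Independent marginal log-likelihood: per-cluster quad integration."""
    total = 0.0
    for _, g in df.groupby("male_id"):
        X = np.column_stack([np.ones(len(g)), g["calling"], g["clutch_present"]])
        y = g["mating_success"].to_numpy(dtype=float)
        eta0 = X @ beta

        def integrand(b):
            eta = eta0 + b
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            return np.exp(ll) * np.exp(-b * b / (2 * sigma ** 2)) / (
                np.sqrt(2 * np.pi) * sigma)

        val, _ = integrate.quad(integrand, -8 * sigma - 5, 8 * sigma + 5,
                                limit=200)
        total += np.log(val)
    return total


class TestLogisticGLMM:
    def test_single_group_equals_plain_logistic(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        nights = simulate_nights(n_males=1, n_nights=200, sigma_male=0.0,
                                 beta0=-1.0, rng=rng)
        fit = fit_logistic_glmm(nights)
        assert fit.random_variances["male_id"] == 0.0
        X = np.column_stack([np.ones(len(nights)), nights["calling"],
                             nights["clutch_present"]])
        ref = sm.Logit(nights["mating_success"].to_numpy(), X).fit(disp=0)
        assert fit.estimates == pytest.approx(ref.params, abs=1e-6)

    def test_agq_matches_dense_grid_oracle(self, rng):
        # 5-male toy set: 15-node AGQ vs adaptive quadrature to 1e-4
        nights = simulate_nights(n_males=5, n_nights=25, beta0=-1.0,
                                 sigma_male=0.8, rng=rng)
        beta = np.array([-0.9, 1.2, 0.4])
        sigma = 0.7
        X = np.column_stack([np.ones(len(nights)), nights["calling"],
                             nights["clutch_present"]])
        y = nights["mating_success"].to_numpy(dtype=float)
        gidx, uniq = pd.factorize(nights["male_id"])
        ours = glmm_marginal_loglik(np.append(beta, np.log(sigma)), X, y,
                                    gidx, uniq.size, n_quad=15)
        oracle = _glmm_nll_grid_oracle(nights, beta, sigma)
        assert ours == pytest.approx(oracle, abs=1e-4)

    def test_laplace_is_one_node(self, rng):
        nights = simulate_nights(n_males=6, n_nights=20, rng=rng)
        X = np.column_stack([np.ones(len(nights)), nights["calling"],
                             nights["clutch_present"]])
        y = nights["mating_success"].to_numpy(dtype=float)
        gidx, uniq = pd.factorize(nights["male_id"])
        theta = np.array([-4.0, 3.0, 0.5, 0.0])
        l1 = glmm_marginal_loglik(theta, X, y, gidx, uniq.size, n_quad=1)
        l15 = glmm_marginal_loglik(theta, X, y, gidx, uniq.size, n_quad=15)
        # Laplace close to, but not identical with, the converged quadrature
        assert l1 == pytest.approx(l15, abs=0.5)
        assert l1 != l15

    def test_effects_recovered_on_simulated_nights(self):
        nights = simulate_nights(rng=np.random.default_rng(321))
        fit = fit_logistic_glmm(nights)
        i = fit.names.index("calling")
        j = fit.names.index("clutch_present")
        assert fit.estimates[i] == pytest.approx(3.5396, abs=2.5 * fit.se[i])
        assert fit.estimates[j] == pytest.approx(0.5671, abs=2.5 * fit.se[j])
        assert 0.1 < fit.random_variances["male_id"] < 10.0

    def test_type_one_error_of_wald_z_under_null(self):
        # beta_clutch = 0: rejection rate of the nominal 5% Wald test
        rejections = 0
        reps = 120
        for s in range(reps):
            nights = simulate_nights(n_males=30, n_nights=15, beta_clutch=0.0,
                                     beta0=-2.0, beta_calling=1.0,
                                     rng=np.random.default_rng(5000 + s))
            try:
                fit = fit_logistic_glmm(nights, n_quad=7)
            except Exception:
                continue
            j = fit.names.index("clutch_present")
            rejections += fit.pvalues[j] < 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.09

    def test_non_binary_response_rejected(self):
        df = pd.DataFrame({"male_id": ["a"] * 4, "calling": [0, 1, 0, 1],
                           "clutch_present": [0, 0, 1, 1],
                           "mating_success": [0, 1, 2, 1]})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic_glmm(df)
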