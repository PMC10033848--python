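"""REML mixed models, heritability, correlations, Wald tests, OLS models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyarch import quantgen as qg
from polyarch import synthdata as sd
from polyarch.relatedness import RelationshipMatrix, compute_grrm, compute_pedigree_a


def balanced_sire_data(s=50, n0=20, sg=2.0, se=3.0, seed=3):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(sg), s)
    y = np.repeat(a, n0) + rng.normal(0, np.sqrt(se), s * n0)
    data = pd.DataFrame({"id": np.repeat([f"s{i}" for i in range(s)], n0), "y": y})
    K = RelationshipMatrix(np.eye(s), [f"s{i}" for i in range(s)], "pedigree")
    return data, K, y.reshape(s, n0)


def anova_reml_closed_form(ymat):
    """Balanced one-way random-effects REML via expected mean squares."""
    s, n0 = ymat.shape
    gm = ymat.mean()
    msb = n0 * ((ymat.mean(axis=1) - gm) ** 2).sum() / (s - 1)
    msw = ((ymat - ymat.mean(axis=1, keepdims=True)) ** 2).sum() / (s * (n0 - 1))
    return (msb - msw) / n0, msw


class TestUnivariateREML:
    def test_matches_balanced_anova_closed_form(self):
        data, K, ymat = balanced_sire_data()
        fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, K)
        sg_cf, se_cf = anova_reml_closed_form(ymat)
        assert fit.converged
        assert fit.varcomp["genetic"] == pytest.approx(sg_cf, abs=1e-6)
        assert fit.varcomp["residual"] == pytest.approx(se_cf, abs=1e-6)

    def test_gblup_h2_recovery(self):
        rng = np.random.default_rng(0)
        h2s = []
        # per-replicate SD of h2-hat is ~0.13 at this size; 20 reps put the
        # standard error of the mean near 0.03
        for rep in range(20):
            D = sd.simulate_founders(400, 1500, ("uniform", 0.05, 0.5), seed=900 + rep)
            G = compute_grrm(D)
            L = np.linalg.cholesky(G.values + 1e-6 * np.eye(400))
            a = L @ rng.normal(0, 1, 400)
            a *= 1.0 / a.std()
            y = a + rng.normal(0, 1, 400)
            data = pd.DataFrame({"id": D.ids, "y": y})
            fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, G)
            h2s.append(qg.estimate_h2(fit).h2)
        assert abs(np.mean(h2s) - 0.5) < 0.08

    def test_zero_genetic_signal_hits_boundary(self, rng):
        n = 300
        D = sd.simulate_founders(n, 500, ("uniform", 0.1, 0.5), seed=7)
        G = compute_grrm(D)
        y = rng.normal(0, 1, n)
        data = pd.DataFrame({"id": D.ids, "y": y})
        fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, G)
        assert fit.varcomp["genetic"] < 0.05 * np.var(y)

    def test_identity_k_recovers_total_variance(self, rng):
        # genetic and residual are confounded; only the sum is identified
        n = 2000
        y = rng.normal(0, 2.0, n)
        ids = [str(i) for i in range(n)]
        K = RelationshipMatrix(np.eye(n), ids, "genomic")
        data = pd.DataFrame({"id": ids, "y": y})
        fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, K)
        total = fit.varcomp["genetic"] + fit.varcomp["residual"]
        assert abs(total - np.var(y)) < 0.05 * np.var(y)

    def test_heterogeneous_residual_by_site(self):
        rng = np.random.default_rng(5)
        n = 900
        D = sd.simulate_founders(n, 800, ("uniform", 0.1, 0.5), seed=8)
        G = compute_grrm(D)
        L = np.linalg.cholesky(G.values + 1e-6 * np.eye(n))
        a = L @ rng.normal(0, 1, n)
        a *= np.sqrt(1.0) / a.std()
        site = np.repeat(["s1", "s2", "s3"], n // 3)
        sd_by_site = {"s1": 1.0, "s2": 2.0, "s3": 0.7}
        y = a + rng.normal(0, 1, n) * np.array([sd_by_site[s] for s in site])
        data = pd.DataFrame({"id": D.ids, "y": y, "site": site})
        spec = qg.ModelSpec(response="y", fixed=["site"], residual="by_site")
        fit = qg.fit_univariate_reml(spec, data, G)
        assert fit.converged
        resid = {k: v for k, v in fit.varcomp.items() if k.startswith("residual")}
        assert len(resid) == 3
        assert resid["residual[s2]"] > resid["residual[s1]"] > resid["residual[s3]"]

    def test_blup_prediction_se_bounds(self):
        data, K, _ = balanced_sire_data(s=30, n0=10, seed=13)
        fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, K)
        assert fit.blup_se is not None
        # PEV is positive and below the prior SD sqrt(sg) for every sire
        assert (fit.blup_se > 0).all()
        assert (fit.blup_se < np.sqrt(fit.sigma_g2)).all()

    def test_constant_response_rejected(self):
        K = RelationshipMatrix(np.eye(3), list("abc"), "genomic")
        data = pd.DataFrame({"id": list("abc"), "y": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, K)


class TestHeritability:
    def test_direct_arithmetic(self):
        fit = _fake_fit({"genetic": 3.0, "residual": 1.0})
        assert qg.estimate_h2(fit).h2 == pytest.approx(0.75)

    def test_mean_of_site_residuals(self):
        fit = _fake_fit({"genetic": 2.0, "residual[a]": 1.0, "residual[b]": 3.0})
        assert qg.estimate_h2(fit).h2 == pytest.approx(0.5)

    def test_delta_se_matches_parametric_bootstrap(self):
        data, K, ymat = balanced_sire_data(s=40, n0=15, sg=1.0, se=2.0, seed=9)
        fit = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, K)
        est = qg.estimate_h2(fit)
        # bootstrap the (verified-equivalent) closed-form estimator
        rng = np.random.default_rng(10)
        sg, se = fit.varcomp["genetic"], fit.varcomp["residual"]
        s, n0 = 40, 15
        h2_draws = []
        for _ in range(2000):
            a = rng.normal(0, np.sqrt(sg), s)
            ysim = a[:, None] + rng.normal(0, np.sqrt(se), (s, n0))
            sg_b, se_b = anova_reml_closed_form(ysim)
            sg_b = max(sg_b, 0.0)
            h2_draws.append(sg_b / (sg_b + se_b))
        boot_se = np.std(h2_draws)
        assert abs(est.se - boot_se) < 0.2 * boot_se


def _fake_fit(varcomp):
    names = list(varcomp)
    return qg.REMLFit(
        spec=qg.ModelSpec(response="y"),
        varcomp=varcomp,
        component_cov=np.eye(len(names)) * 1e-4,
        component_names=names,
        beta=np.zeros(1),
        beta_cov=np.eye(1),
        beta_names=["(Intercept)"],
        term_slices={"(Intercept)": [0]},
        blup=pd.Series(dtype=float),
        blup_se=None,
        loglik=0.0,
        converged=True,
        n_iter=1,
        n_obs=10,
        rank_x=1,
    )


class TestBivariateREML:
    def test_zero_genetic_covariance_gives_zero_rg(self):
        rng = np.random.default_rng(11)
        n = 300
        D = sd.simulate_founders(n, 800, ("uniform", 0.1, 0.5), seed=12)
        G = compute_grrm(D)
        L = np.linalg.cholesky(G.values + 1e-6 * np.eye(n))
        a1 = L @ rng.normal(0, 1, n)
        a2 = L @ rng.normal(0, 1, n)
        data = pd.DataFrame({
            "id": D.ids,
            "t1": a1 + rng.normal(0, 1, n),
            "t2": a2 + rng.normal(0, 1, n),
        })
        est = qg.fit_bivariate_reml(
            qg.ModelSpec(response="t1", fixed=[]), qg.ModelSpec(response="t2", fixed=[]), data, G
        )
        assert abs(est.r_g) < 3 * est.r_g_se + 0.05

    def test_rg_recovery(self):
        rng = np.random.default_rng(13)
        rgs = []
        for rep in range(8):
            n = 500
            D = sd.simulate_founders(n, 1000, ("uniform", 0.05, 0.5), seed=300 + rep)
            G = compute_grrm(D)
            L = np.linalg.cholesky(G.values + 1e-6 * np.eye(n))
            G0 = np.array([[0.4, 0.28], [0.28, 0.4]])  # r_g = 0.7, h2 = 0.4
            A = L @ rng.normal(0, 1, (n, 2)) @ np.linalg.cholesky(G0).T
            Y = A + rng.normal(0, np.sqrt(0.6), (n, 2))
            data = pd.DataFrame({"id": D.ids, "t1": Y[:, 0], "t2": Y[:, 1]})
            est = qg.fit_bivariate_reml(
                qg.ModelSpec(response="t1", fixed=[]),
                qg.ModelSpec(response="t2", fixed=[]),
                data,
                G,
            )
            rgs.append(est.r_g)
        assert abs(np.mean(rgs) - 0.7) < 0.1

    def test_rp_equals_sample_correlation_without_genetics(self, rng):
        n = 800
        ids = [str(i) for i in range(n)]
        K = RelationshipMatrix(np.eye(n), ids, "genomic")
        Y = rng.multivariate_normal([0, 0], [[1.0, 0.5], [0.5, 1.0]], n)
        data = pd.DataFrame({"id": ids, "t1": Y[:, 0], "t2": Y[:, 1]})
        est = qg.fit_bivariate_reml(
            qg.ModelSpec(response="t1", fixed=[]), qg.ModelSpec(response="t2", fixed=[]), data, K
        )
        assert abs(est.r_p - np.corrcoef(Y.T)[0, 1]) < 0.02


class TestAdjustedPhenotypes:
    def test_intercept_only_centres(self, rng):
        y = rng.normal(5, 1, 50)
        data = pd.DataFrame({"id": [str(i) for i in range(50)], "y": y})
        adj = qg.adjust_phenotypes(qg.ModelSpec(response="y", fixed=[]), data)
        assert np.allclose(adj.residuals, y - y.mean())

    def test_site_effects_removed(self, rng):
        n = 300
        site = rng.choice(["a", "b", "c"], n)
        y = rng.normal(0, 1, n) + pd.Series(site).map({"a": 0, "b": 5, "c": -3}).to_numpy()
        data = pd.DataFrame({"id": [str(i) for i in range(n)], "y": y, "site": site})
        adj = qg.adjust_phenotypes(qg.ModelSpec(response="y", fixed=["site"]), data)
        for s in "abc":
            assert abs(adj.residuals[site == s].sum()) < 1e-8
        # regressing the residual on site indicators recovers ~0 coefficients
        fit = qg.fit_ols(data.assign(r=adj.residuals.to_numpy()), "r", ["site"])
        assert np.all(np.abs(fit.beta[1:]) < 1e-8)


class TestWald:
    def test_single_coefficient_equals_squared_t(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        data = pd.DataFrame({"x": x, "y": y})
        fit = qg.fit_ols(data, "y", ["x"])
        w = qg.wald_test(fit, "x")
        i = fit.beta_names.index("x")
        t = fit.beta[i] / np.sqrt(fit.beta_cov[i, i])
        assert w.f_stat == pytest.approx(t**2)
        assert w.df_num == 1

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        n = 60
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            fit = qg.fit_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            rejections += qg.wald_test(fit, "x").p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_planted_effect(self, rng):
        n = 1000
        x = rng.normal(0, 1, n)
        y = 1.0 * x + rng.normal(0, 1, n)
        fit = qg.fit_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert qg.wald_test(fit, "x").p_value < 1e-6

    def test_unknown_term_raises(self, rng):
        fit = qg.fit_ols(pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)}), "y", ["x"])
        with pytest.raises(KeyError):
            qg.wald_test(fit, "z")


class TestInbreedingDepression:
    def test_planted_depression_recovered(self):
        rng = np.random.default_rng(30)
        hits = 0
        reps = 12
        for rep in range(reps):
            n = 600
            D = sd.simulate_founders(n, 600, ("uniform", 0.1, 0.5), seed=700 + rep)
            G = compute_grrm(D)
            L = np.linalg.cholesky(G.values + 1e-6 * np.eye(n))
            a = L @ rng.normal(0, 1, n)
            F = rng.uniform(-0.05, 0.25, n)
            y = 100.0 - 50.0 * F + a + rng.normal(0, 1, n)
            data = pd.DataFrame({"id": D.ids, "y": y, "f_uni": F})
            row = qg.estimate_inbreeding_depression("y", data, G)
            hits += abs(row.estimate - (-50.0)) < 2 * row.se
        assert hits / reps >= 0.9

    def test_null_calibration(self):
        rng = np.random.default_rng(31)
        cover = 0
        reps = 20
        ids = [str(i) for i in range(400)]
        K = RelationshipMatrix(np.eye(400), ids, "genomic")
        for _ in range(reps):
            F = rng.uniform(0, 0.3, 400)
            y = rng.normal(0, 1, 400)
            data = pd.DataFrame({"id": ids, "y": y, "f_uni": F})
            row = qg.estimate_inbreeding_depression("y", data, K)
            cover += abs(row.estimate) < 2 * row.se
        assert cover / reps >= 0.8

    def test_report_columns(self, rng):
        ids = [str(i) for i in range(100)]
        K = RelationshipMatrix(np.eye(100), ids, "genomic")
        data = pd.DataFrame({
            "id": ids, "y": rng.normal(0, 1, 100), "f_uni": rng.uniform(0, 0.5, 100)
        })
        row = qg.estimate_inbreeding_depression("y", data, K)
        assert {"trait", "estimate", "se", "f_stat", "p_value"} <= set(vars(row))

    def test_constant_f_rejected(self, rng):
        ids = [str(i) for i in range(50)]
        K = RelationshipMatrix(np.eye(50), ids, "genomic")
        data = pd.DataFrame({"id": ids, "y": rng.normal(0, 1, 50), "f_uni": 0.1})
        with pytest.raises(ValueError):
            qg.estimate_inbreeding_depression("y", data, K)


class TestSelfingOLS:
    def test_null_slope(self, rng):
        df = pd.DataFrame({
            "bv": rng.normal(0, 1, 200),
            "F": rng.uniform(0, 1, 200),
            "line_type": rng.choice(["select", "random"], 200),
            "family": rng.integers(0, 10, 200),
        })
        fit = qg.fit_selfing_ols(df, "simple")
        assert abs(fit.coef("F")) < 2 * fit.se("F")

    def test_simple_slope_is_least_squares_slope(self, rng):
        F = rng.uniform(0, 1, 150)
        y = 3.0 - 2.0 * F + rng.normal(0, 0.5, 150)
        df = pd.DataFrame({"bv": y, "F": F, "line_type": "random", "family": 0})
        fit = qg.fit_selfing_ols(df, "simple")
        slope = np.cov(y, F)[0, 1] / np.var(F, ddof=1)
        assert fit.coef("F") == pytest.approx(slope)

    def test_interaction_recovers_slope_difference(self, rng):
        n = 400
        F = rng.uniform(0, 1, n)
        lt = np.where(np.arange(n) % 2 == 0, "random", "select")
        fam = rng.integers(0, 15, n)
        slope = np.where(lt == "random", -10.0, 5.0)
        y = 50.0 + slope * F + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"bv": y, "F": F, "line_type": lt, "family": fam})
        fit = qg.fit_selfing_ols(df, "selection")
        term = "F:line_type[select]"
        assert abs(fit.coef(term) - 15.0) < 2 * fit.se(term)

    def test_diagnostics_emitted(self, rng):
        df = pd.DataFrame({
            "bv": rng.normal(0, 1, 50), "F": rng.uniform(0, 1, 50),
            "line_type": "random", "family": 0,
        })
        fit = qg.fit_selfing_ols(df, "simple")
        assert {"resid_skew", "resid_kurtosis", "abs_resid_fitted_corr"} <= set(fit.diagnostics)


class TestOLSCrossCheck:
    def test_selection_model_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf

        n = 200
        F = rng.uniform(0, 1, n)
        lt = rng.choice(["random", "select"], n)
        fam = rng.integers(0, 8, n)
        y = 10 - 4 * F + 2 * (lt == "select") * F + rng.normal(0, 1, n)
        df = pd.DataFrame({"bv": y, "F": F, "line_type": lt, "family": fam})
        ours = qg.fit_selfing_ols(df, "selection")
        sm_fit = smf.ols(
            "bv ~ F + C(line_type) + F:C(line_type) + C(family)", data=df
        ).fit()
        assert ours.coef("F:line_type[select]") == pytest.approx(
            sm_fit.params["F:C(line_type)[T.select]"], rel=1e-8
        )
        assert ours.se("F:line_type[select]") == pytest.approx(
            sm_fit.bse["F:C(line_type)[T.select]"], rel=1e-6
        )


class TestGBLUPEstimator:
    def test_fit_attributes_and_params(self):
        rng = np.random.default_rng(60)
        D = sd.simulate_founders(300, 600, ("uniform", 0.1, 0.5), seed=60)
        G = compute_grrm(D)
        L = np.linalg.cholesky(G.values + 1e-6 * np.eye(300))
        a = L @ rng.normal(0, 1, 300)
        a *= 1.0 / a.std()
        y = a + rng.normal(0, 1, 300)
        est = qg.GBLUPRegressor().fit(D, y)
        assert 0.2 < est.h2_ < 0.8
        assert est.sigma_g2_ > 0 and est.sigma_e2_ > 0
        assert qg.GBLUPRegressor(**est.get_params()).get_params() == est.get_params()
        # in-sample predictions correlate with the simulated breeding values
        pred = est.predict(D)
        assert np.corrcoef(pred, a)[0, 1] > 0.5
        assert est.score(D, y) > 0.0

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError):
            qg.GBLUPRegressor().predict(np.zeros((2, 3)))


class TestABLUPvsGBLUP:
    def test_bv_rankings_agree(self):
        rng = np.random.default_rng(40)
        founders = sd.simulate_founders(50, 2000, ("uniform", 0.1, 0.5), seed=50)
        prog, ped = sd.simulate_polycross_progeny(founders, 25, 20, 1, seed=51)
        arch = sd.draw_true_architecture(2000, (0.8, 0.14, 0.04, 0.02), 1.0, seed=52)
        ph = sd.simulate_phenotypes(prog, arch, np.zeros(500, int), [0.0], [0.0], seed=53)
        bv = ph["true_bv"].to_numpy()
        bv = (bv - bv.mean()) / bv.std()
        y = bv + rng.normal(0, 1, 500)  # h2 = 0.5
        data = pd.DataFrame({"id": prog.ids, "y": y})
        G = compute_grrm(prog)
        fit_g = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, G)
        full_ped = pd.concat(
            [
                pd.DataFrame({"id": founders.ids, "sire": None, "dam": None}),
                ped[["id", "sire", "dam"]],
            ],
            ignore_index=True,
        )
        A = compute_pedigree_a(full_ped)
        fit_a = qg.fit_univariate_reml(qg.ModelSpec(response="y", fixed=[]), data, A)
        rho = stats.spearmanr(fit_g.blup[prog.ids], fit_a.blup[prog.ids]).statistic
        assert rho >= 0.8
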