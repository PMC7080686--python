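"""Design building, GLM/OLS/logistic fits and cluster-robust inference."""

import numpy as np
import pandas as pd
import pytest

from vertclaims.estimation import (
    ClusterRobustLogit,
    ClusterRobustOLS,
    EstimationError,
    QuasiPoissonGLM,
    SeparationError,
    assemble_analytic,
    build_design,
    cluster_sandwich,
    fit_glm_log,
    fit_linear_dollars,
    fit_logistic_quality,
    price_utilization_decomposition,
)


def _analytic_frame(n=400, seed=0, n_orgs=8):
    """Small analytic frame with the columns build_design expects."""
    rng = np.random.default_rng(seed)
    org = rng.integers(0, n_orgs, n)
    own = np.where(org % 4 == 0, "local_hospital_owned", "physician_owned")
    msa = rng.choice(["austin", "dallas"], n)
    year = rng.choice([2014, 2015, 2016], n)
    wage = 0.9 + 0.05 * (msa == "dallas") + 0.002 * (year - 2014)
    df = pd.DataFrame(
        {
            "member_id": [f"M{i}" for i in range(n)],
            "year": year,
            "org_id": [f"O{g}" for g in org],
            "ownership": own,
            "hosp": (own != "physician_owned").astype(int),
            "msa": msa,
            "age": rng.integers(19, 65, n),
            "sex": rng.choice(["F", "M"], n),
            "risk_score": rng.lognormal(0, 0.5, n),
            "cdhp_flag": rng.random(n) < 0.3,
            "wage_index": wage,
            "size_category": 1 + (org % 2),
            "n_attributed": 100 + 17 * org,
            "pcp_specialty": rng.choice(["internal_medicine", "family_practice"], n),
        }
    )
    df["y"] = rng.lognormal(np.log(4000) + 0.058 * df["hosp"], 0.8)
    return df


class TestGLM:
    def test_two_group_closed_form(self):
        y = np.array([2.0, 4.0, 6.0, 10.0, 20.0, 30.0])
        X = pd.DataFrame({"hospital_owned": [0, 0, 0, 1, 1, 1.0]})
        m = QuasiPoissonGLM().fit(X, y)
        b = m.coef_[0]
        assert b == pytest.approx(np.log(20.0 / 4.0), abs=1e-8)

    def test_exact_loglinear_fixed_point(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        beta = np.array([0.3, 0.5, -0.2])
        y = np.exp(beta[0] + X.values @ beta[1:])
        m = QuasiPoissonGLM().fit(X, y)
        assert np.allclose(m.params_, beta, atol=1e-8)

    def test_all_zero_response_errors(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(EstimationError, match="zero"):
            QuasiPoissonGLM().fit(X, np.zeros(2))

    def test_negative_response_errors(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(EstimationError, match="non-negative"):
            QuasiPoissonGLM().fit(X, np.array([-1.0, 2.0]))

    def test_gamma_variance_option_runs(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = rng.gamma(2.0, np.exp(1 + 0.5 * X["x"].values) / 2.0)
        m = QuasiPoissonGLM(variance="mean_squared").fit(X, y)
        assert m.coef_[0] == pytest.approx(0.5, abs=0.2)


class TestSandwich:
    def test_matches_brute_force_per_cluster(self):
        """CR0 sandwich equals an explicit per-cluster score-outer-product
        computation on a 5-cluster fixture."""
        rng = np.random.default_rng(3)
        n = 60
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = rng.poisson(np.exp(0.5 + 0.3 * X["x1"].values))
        clusters = np.repeat(np.arange(5), 12)
        m = QuasiPoissonGLM(cluster_correction="cr0").fit(X, y, clusters=clusters)

        Xa = np.hstack([np.ones((n, 1)), X.values])
        mu = np.exp(Xa @ m.params_)
        A = Xa.T @ (Xa * mu[:, None])
        B = np.zeros((3, 3))
        for g in range(5):
            sel = clusters == g
            s_g = Xa[sel].T @ (y[sel] - mu[sel])
            B += np.outer(s_g, s_g)
        V = np.linalg.inv(A) @ B @ np.linalg.inv(A) * (5 / 4)
        assert np.max(np.abs(V - m.cov_)) <= 1e-8 * (1 + np.max(np.abs(V)))

    def test_reduces_to_hc0_with_singleton_clusters(self):
        rng = np.random.default_rng(4)
        n = 40
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(2 + X["x"].values, 1.0)
        m = ClusterRobustOLS(small_sample=False, cluster_correction="cr0").fit(X, y)  # clusters default: singletons
        Xa = np.hstack([np.ones((n, 1)), X.values])
        u = y - Xa @ m.params_
        bread = np.linalg.inv(Xa.T @ Xa)
        hc0 = bread @ (Xa.T @ (Xa * (u**2)[:, None])) @ bread
        assert np.allclose(m.cov_, hc0, atol=1e-12)


class TestOLS:
    def test_exact_linear_zero_residuals_and_ses(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = 2 + 3 * X["x"].values
        m = ClusterRobustOLS().fit(X, y)
        assert np.allclose(m.resid_, 0, atol=1e-10)
        assert np.allclose(m.se_, 0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        y = rng.normal(size=20)
        m = ClusterRobustOLS().fit(X, y)
        Xa = np.hstack([np.ones((20, 1)), X.values])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        assert np.allclose(m.params_, beta, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "twice_a": [2.0, 4, 6, 8]})
        with pytest.raises(EstimationError, match="twice_a"):
            ClusterRobustOLS().fit(X, np.ones(4))


class TestLogit:
    def test_2x2_cross_product_odds_ratio(self):
        # exposure x outcome: a=40, b=10, c=20, d=30 -> OR = 40*30/(10*20) = 6
        y = np.concatenate([np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)])
        x = np.concatenate([np.ones(50), np.zeros(50)])
        m = ClusterRobustLogit().fit(pd.DataFrame({"hospital_owned": x}), y)
        assert np.exp(m.coef_[0]) == pytest.approx(6.0, abs=1e-6)

    def test_matches_direct_likelihood_optimum(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300)})
        eta = 0.2 + 0.8 * X["x1"].values - 0.5 * X["x2"].values
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        m = ClusterRobustLogit().fit(X, y)

        from scipy.optimize import minimize

        Xa = np.hstack([np.ones((300, 1)), X.values])

        def nll(b):
            z = Xa @ b
            return np.sum(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y * z)

        res = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(m.params_, res.x, atol=1e-6)

    def test_separation_raises(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = pd.DataFrame({"x": [-3.0, -2, -1, 1, 2, 3]})
        with pytest.raises(SeparationError):
            ClusterRobustLogit().fit(X, y)

    def test_null_coverage_of_unit_odds_ratio(self):
        """With outcome independent of exposure, the 95% cluster-robust CI
        covers OR=1 in at least 93% of null replicates."""
        rng = np.random.default_rng(7)
        cover = 0
        reps = 200
        for _ in range(reps):
            n = 400
            clusters = rng.integers(0, 30, n)
            x = (clusters % 3 == 0).astype(float)
            y = (rng.random(n) < 0.4).astype(float)
            m = ClusterRobustLogit().fit(pd.DataFrame({"hospital_owned": x}), y,
                                         clusters=clusters)
            lo, hi = m.conf_int("hospital_owned")
            cover += lo <= 0 <= hi
        assert cover / reps >= 0.93


class TestBuildDesign:
    def test_msa_year_interaction_cells(self):
        df = _analytic_frame()
        d = build_design(df, "y")
        cells = [c for c in d.X.columns if c.startswith("msa_year[")]
        assert len(cells) == 5  # 2 MSAs x 3 years minus reference

    def test_degenerate_factor_dropped_and_logged(self):
        df = _analytic_frame()
        df["risk_score"] = 1.0  # single decile
        d = build_design(df, "y")
        assert not any(c.startswith("risk_decile") for c in d.X.columns)
        assert any("risk_decile" in n for n in d.notes)

    def test_column_count_matches_patsy_oracle(self):
        patsy = pytest.importorskip("patsy")
        df = _analytic_frame()
        d = build_design(df, "y", include_wage=False)
        df2 = df.copy()
        df2["msa_year"] = df2["msa"] + ":" + df2["year"].astype(str)
        df2["age_band"] = pd.cut(df2["age"], [19, 30, 40, 55, 65], right=False).astype(str)
        df2["risk_decile"] = pd.qcut(df2["risk_score"], 10, labels=False)
        formula = (
            "hosp + C(msa_year) + C(age_band) + C(sex) + C(risk_decile) "
            "+ cdhp_flag + C(size_category) + C(pcp_specialty)"
        )
        mat = patsy.dmatrix(formula, df2)
        assert mat.shape[1] == d.X.shape[1] + 1  # patsy includes the intercept

    def test_wage_index_aliased_by_msa_year_cells_is_pruned(self):
        df = _analytic_frame()
        d = build_design(df, "y", include_wage=True)
        assert "wage_index" in d.dropped or "wage_index" in d.X.columns
        # wage varies only at the MSA-year level here, so it must be pruned
        assert "wage_index" in d.dropped

    def test_quadratic_age_and_decile_size_bins(self):
        df = _analytic_frame()
        d = build_design(df, "y", age_spec="quadratic", size_bins="decile")
        assert "age_sq" in d.X.columns


class TestEffectWrappers:
    def test_glm_and_ols_effects_run(self):
        df = _analytic_frame(n=600, seed=8)
        d = build_design(df, "y")
        est, m = fit_glm_log(d)
        assert est.estimand == "percent_diff"
        assert est.ci_low <= est.point <= est.ci_high
        est2, _ = fit_linear_dollars(d)
        assert est2.estimand == "dollar_diff"
        assert est2.n_clusters == d.n_clusters

    def test_three_level_coding_and_equality_test(self):
        df = _analytic_frame(n=600, seed=9)
        df.loc[df["org_id"] == "O1", "ownership"] = "multi_hospital_system_owned"
        df["hosp"] = (df["ownership"] != "physician_owned").astype(int)
        d = build_design(df, "y", ownership="three_level")
        m = QuasiPoissonGLM().fit(d.X, d.y, clusters=d.clusters)
        t, p = m.wald_equal("local_hospital_owned", "multi_hospital_system_owned")
        assert 0 <= p <= 1

    def test_decomposition_requires_same_sample(self):
        df = _analytic_frame(n=200, seed=10)
        d1 = build_design(df, "y")
        est1, _ = fit_glm_log(d1)
        d2 = build_design(df.iloc[:150], "y")
        est2, _ = fit_glm_log(d2)
        with pytest.raises(EstimationError, match="sample"):
            price_utilization_decomposition(est1, est2, d1, d2)
        rep = price_utilization_decomposition(est1, est1, d1, d1)
        assert rep.price_effect_pct == 0.0


def test_sensitivity_specification_is_stable(medium_data, medium_study):
    """Decile practice-size bins plus quadratic age give an effect of the same
    sign with an overlapping confidence interval."""
    attr, spend, _, sizes = medium_study
    an = assemble_analytic(attr, spend, medium_data.members,
                          medium_data.wage_index, sizes)
    an["total_dollars"] = an["total_cents"] / 100.0
    base, _ = fit_glm_log(build_design(an, "total_dollars"))
    alt, _ = fit_glm_log(
        build_design(an, "total_dollars", age_spec="quadratic", size_bins="decile")
    )
    assert np.sign(base.point) == np.sign(alt.point)
    assert base.ci_low <= alt.ci_high and alt.ci_low <= base.ci_high
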