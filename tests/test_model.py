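import copy
import dataclasses

import numpy as np
import pandas as pd
import pytest

from normdev.model import HierarchicalNormativeModel
from normdev.simulate import CohortSimulator, GeneratorConfig

from conftest import zeroed_config


def _toy_frame(n, rng, site="s0"):
    return pd.DataFrame({
        "age": rng.uniform(40, 90, n),
        "sex": rng.choice(["female", "male"], n),
        "site": site,
    })


class TestFitReference:
    def test_noiseless_coefficients_recovered_exactly(self, rng):
        """With no noise and no site effects, betas are identified exactly."""
        n = 60
        X = pd.concat([_toy_frame(n // 2, rng, "a"), _toy_frame(n // 2, rng, "b")],
                      ignore_index=True)
        beta = np.array([[2.5, -0.005, 0.02], [2.2, -0.003, -0.04]])  # 2 regions
        female = (X["sex"] == "female").astype(float)
        Y = pd.DataFrame({
            f"r{j}": beta[j, 0] + beta[j, 1] * X["age"] + beta[j, 2] * female
            for j in range(2)})
        est = HierarchicalNormativeModel(regions="columns").fit(X, Y)
        # intercept is reported at the centred-age origin
        expected_intercepts = beta[:, 0] + beta[:, 1] * est.age_center_
        np.testing.assert_allclose(est.coef_[:, 0], expected_intercepts, atol=1e-6)
        np.testing.assert_allclose(est.coef_[:, 1], beta[:, 1], atol=1e-6)
        np.testing.assert_allclose(est.coef_[:, 2], beta[:, 2], atol=1e-6)

    def test_row_permutation_invariant(self, small_sim):
        cohort, thick = small_sim.reference()
        perm = np.random.default_rng(0).permutation(len(cohort))
        a = HierarchicalNormativeModel().fit(cohort, thick)
        b = HierarchicalNormativeModel().fit(
            cohort.iloc[perm].reset_index(drop=True), thick.iloc[perm])
        np.testing.assert_allclose(a.coef_, b.coef_, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(a.site_sigma2_, b.site_sigma2_, rtol=1e-10)

    def test_single_site_rejected(self, rng):
        X = _toy_frame(30, rng, "only")
        Y = pd.DataFrame({"r0": rng.normal(2.5, 0.1, 30)})
        with pytest.raises(ValueError, match="2 sites"):
            HierarchicalNormativeModel(regions="columns").fit(X, Y)

    def test_nonfinite_thickness_named(self, rng):
        X = pd.concat([_toy_frame(10, rng, "a"), _toy_frame(10, rng, "b")],
                      ignore_index=True)
        Y = pd.DataFrame({"r0": rng.normal(2.5, 0.1, 20)})
        Y.iloc[3, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            HierarchicalNormativeModel(regions="columns").fit(X, Y)

    def test_age_slopes_recovered_with_coverage(self, small_sim, _fitted_base):
        est = _fitted_base
        se = np.sqrt(est.coef_cov_[:, 1, 1])
        covered = np.abs(est.coef_[:, 1] - small_sim.truth.age_slope) <= 1.96 * se
        assert covered.mean() >= 0.85  # n=800 reference

    def test_gibbs_backend_agrees_with_eb(self, small_sim):
        cohort, thick = small_sim.reference()
        sub = thick.iloc[:, :10]
        eb = HierarchicalNormativeModel(regions="columns").fit(cohort, sub)
        gb = HierarchicalNormativeModel(regions="columns", backend="gibbs",
                                        draws=300, warmup=300,
                                        random_state=5).fit(cohort, sub)
        se = np.sqrt(eb.coef_cov_[:, 1, 1])
        assert np.all(np.abs(eb.coef_[:, 1] - gb.coef_[:, 1]) < 4 * se)
        assert gb.diagnostics_["backend"] == "gibbs"
        assert max(gb.diagnostics_["rhat_age_slope"]) < 1.1

    def test_gibbs_deterministic_under_seed(self, small_sim):
        cohort, thick = small_sim.reference()
        sub = thick.iloc[:, :5]
        kw = dict(regions="columns", backend="gibbs", draws=150, warmup=150,
                  random_state=11)
        a = HierarchicalNormativeModel(**kw).fit(cohort, sub)
        b = HierarchicalNormativeModel(**kw).fit(cohort, sub)
        np.testing.assert_array_equal(a.coef_, b.coef_)


class TestAdaptation:
    def test_large_n_offset_recovered(self):
        """Posterior site offset converges to a forced +0.1 mm shift."""
        sim = CohortSimulator(GeneratorConfig(seed=2, n_adaptation=2000))
        sim.truth.clinical_site_offset = np.full(148, 0.1)
        est = HierarchicalNormativeModel().fit(*sim.reference())
        est.adapt(*sim.adaptation())
        u = est.adaptation_["u_mean"]
        assert abs(u.mean() - 0.1) < 0.005
        # per-region error also carries the reference fit's intercept noise
        assert np.abs(u - 0.1).max() < 0.08

    def test_null_site_offset_near_zero(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        u = fitted.adaptation_["u_mean"]
        # true offsets are N(0, 0.05^2); posterior means shrink toward 0
        assert np.abs(u - small_sim.truth.clinical_site_offset).mean() < 0.05

    def test_adapt_deterministic(self, fitted, small_sim):
        other = copy.deepcopy(fitted)
        fitted.adapt(*small_sim.adaptation())
        other.adapt(*small_sim.adaptation())
        np.testing.assert_array_equal(fitted.adaptation_["u_mean"],
                                      other.adaptation_["u_mean"])

    def test_known_site_reused_with_warning(self, fitted, small_sim):
        cohort, thick = small_sim.reference()
        site = fitted.sites_[0]
        mask = (cohort["site"] == site).to_numpy()
        with pytest.warns(UserWarning, match="already in the reference"):
            fitted.adapt(cohort[mask].head(10), thick.iloc[mask].head(10))
        s = fitted.sites_.index(site)
        np.testing.assert_array_equal(fitted.adaptation_["u_mean"],
                                      fitted.site_offset_mean_[s])

    def test_too_few_subjects_rejected(self, fitted, small_sim):
        cohort, thick = small_sim.adaptation()
        with pytest.raises(ValueError, match=">= 2"):
            fitted.adapt(cohort.head(1), thick.head(1))


class TestScoring:
    def test_centering_and_threshold_boundary(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(5)
        cohort = cohort.set_index("subject_id")
        res0 = fitted.deviation_scores(cohort, thick)
        # y == mu  ->  z == 0
        z0 = fitted.deviation_scores(cohort, res0.mu)
        np.testing.assert_allclose(z0.z.to_numpy(), 0.0, atol=1e-12)
        # y == mu - 1.96 sd  ->  z == -1.96 exactly (outlier boundary)
        y = res0.mu - 1.96 * res0.sd
        zb = fitted.deviation_scores(cohort, y)
        np.testing.assert_allclose(zb.z.to_numpy(), -1.96, atol=1e-12)

    def test_monotone_in_thickness(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(3)
        cohort = cohort.set_index("subject_id")
        z_hi = fitted.deviation_scores(cohort, thick).z.to_numpy()
        z_lo = fitted.deviation_scores(cohort, thick - 0.01).z.to_numpy()
        assert (z_lo < z_hi).all()

    def test_null_scores_calibrated(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(200)
        z = fitted.deviation_scores(cohort.set_index("subject_id"), thick).z.to_numpy()
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.05

    def test_extrapolated_subjects_flagged_but_scored(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(3)
        cohort = cohort.set_index("subject_id")
        cohort.loc[cohort.index[0], "age"] = 140.0
        res = fitted.deviation_scores(cohort, thick)
        assert bool(res.extrapolated.iloc[0]) is True
        assert not res.extrapolated.iloc[1:].any()
        assert np.isfinite(res.z.to_numpy()).all()

    def test_transfer_consistency_with_identical_site(self, small_sim):
        """Adapting on data from a reference site's distribution reproduces
        that site's scores within Monte-Carlo tolerance."""
        cohort, thick = small_sim.reference()
        est = HierarchicalNormativeModel().fit(cohort, thick)
        site = est.sites_[2]
        mask = (cohort["site"] == site).to_numpy()
        test_c = cohort[mask].head(30).set_index("subject_id")
        test_t = thick.iloc[mask].head(30)
        z_ref = est.deviation_scores(test_c, test_t).z.to_numpy()
        # relabel the remaining rows of the same site as a "new" site
        ad_c = cohort[mask].iloc[30:].assign(site="site_new")
        ad_t = thick.iloc[mask].iloc[30:]
        est.adapt(ad_c, ad_t)
        z_new = est.deviation_scores(test_c.assign(site="site_new"), test_t).z.to_numpy()
        assert np.abs(z_new - z_ref).mean() < 0.15
        assert np.corrcoef(z_new.ravel(), z_ref.ravel())[0, 1] > 0.99

    def test_unknown_site_rejected(self, fitted, small_sim):
        cohort, thick = small_sim.holdout(3)
        with pytest.raises(ValueError, match="unknown"):
            fitted.deviation_scores(cohort.set_index("subject_id"), thick)


class TestOracleEquivalence:
    def test_degenerate_sites_match_linear_regression_closed_form(self, rng):
        """Two identical pseudo-sites reduce to ordinary Bayesian linear
        regression: mu and sd match the closed-form solution."""
        n = 25
        Xa = _toy_frame(n, rng, "site_a")
        beta = np.array([2.5, -0.004, 0.03])
        female = (Xa["sex"] == "female").astype(float).to_numpy()
        y = (beta[0] + beta[1] * Xa["age"].to_numpy() + beta[2] * female
             + rng.normal(0, 0.1, n))
        X2 = pd.concat([Xa, Xa.assign(site="site_b")], ignore_index=True)
        Y2 = pd.DataFrame({"r0": np.concatenate([y, y])})
        est = HierarchicalNormativeModel(regions="columns").fit(X2, Y2)

        # independent closed form on the duplicated design
        D = np.column_stack([np.ones(2 * n),
                             X2["age"].to_numpy() - est.age_center_,
                             np.concatenate([female, female])])
        yy = Y2["r0"].to_numpy()
        bhat = np.linalg.solve(D.T @ D, D.T @ yy)
        resid = yy - D @ bhat
        s2 = (resid**2).sum() / (2 * n)
        Vb = s2 * np.linalg.inv(D.T @ D)

        new = Xa.head(8)
        Dn = np.column_stack([np.ones(8), new["age"].to_numpy() - est.age_center_,
                              female[:8]])
        mu_oracle = Dn @ bhat
        sd_oracle = np.sqrt(s2 + np.einsum("ni,ij,nj->n", Dn, Vb, Dn))
        res = est.deviation_scores(new, pd.DataFrame({"r0": y[:8]}))
        np.testing.assert_allclose(res.mu.to_numpy()[:, 0], mu_oracle, atol=1e-3)
        np.testing.assert_allclose(res.sd.to_numpy()[:, 0], sd_oracle, atol=1e-3)


class TestSerialization:
    def test_json_roundtrip_preserves_scores(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(5)
        cohort = cohort.set_index("subject_id")
        z1 = fitted.deviation_scores(cohort, thick).z
        est2 = HierarchicalNormativeModel.from_json(fitted.to_json())
        z2 = est2.deviation_scores(cohort, thick).z
        pd.testing.assert_frame_equal(z1, z2)

    def test_plugin_predictive_narrower(self, fitted, small_sim):
        fitted.adapt(*small_sim.adaptation())
        cohort, thick = small_sim.holdout(5)
        cohort = cohort.set_index("subject_id")
        sd_post = fitted.deviation_scores(cohort, thick).sd.to_numpy()
        fitted.predictive = "plugin"
        sd_plug = fitted.deviation_scores(cohort, thick).sd.to_numpy()
        assert (sd_plug < sd_post).all()
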