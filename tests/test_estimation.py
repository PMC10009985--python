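"""Conditional logit, Halton draws, mixed logit and latent-class EM."""

import numpy as np
import pandas as pd
import pytest

import ruraldce as r
from ruraldce.data import Attribute, AttributeSchema
from ruraldce.estimation import (
    _panel_index,
    clogit_loglik,
    halton_normal_draws,
    halton_sequence,
    mixl_simulated_loglik,
)
from ruraldce.simulate import REFERENCE_LCM_SHARES, REFERENCE_MIXL_MEANS, REFERENCE_MIXL_SDS


class TestClogitLoglik:
    def test_null_loglik_closed_form(self, mixl_dataset, schema):
        dx, y, _ = r.paired_differences(mixl_dataset, schema)
        ll, _, _ = clogit_loglik(np.zeros(dx.shape[1]), dx, y)
        assert ll == pytest.approx(5632 * np.log(0.5), abs=1e-8)

    def test_dominant_utility_loglik_approaches_zero(self):
        dx = np.array([[1.0]])
        y = np.array([1.0])
        ll, _, _ = clogit_loglik(np.array([50.0]), dx, y)
        assert -1e-10 < ll <= 0.0

    def test_gradient_matches_finite_differences(self, mixl_dataset, schema):
        dx, y, _ = r.paired_differences(mixl_dataset, schema)
        dxn = dx / dx.std(axis=0)  # common scale so one step size fits all
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.5, dx.shape[1])
        _, grad, hess = clogit_loglik(beta, dxn, y)
        eps = 1e-6
        for k in range(len(beta)):
            e = np.zeros_like(beta)
            e[k] = eps
            lp, _, _ = clogit_loglik(beta + e, dxn, y)
            lm, _, _ = clogit_loglik(beta - e, dxn, y)
            assert grad[k] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-4)

    def test_hessian_matches_gradient_differences(self, mixl_dataset, schema):
        dx, y, _ = r.paired_differences(mixl_dataset, schema)
        dxn = dx / dx.std(axis=0)
        beta = np.full(dxn.shape[1], 0.3)
        _, _, hess = clogit_loglik(beta, dxn, y)
        eps = 1e-6
        for k in range(len(beta)):
            e = np.zeros_like(beta)
            e[k] = eps
            _, gp, _ = clogit_loglik(beta + e, dxn, y)
            _, gm, _ = clogit_loglik(beta - e, dxn, y)
            np.testing.assert_allclose(hess[:, k], (gp - gm) / (2 * eps), rtol=1e-4, atol=1e-3)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            clogit_loglik(np.array([np.nan]), np.ones((1, 1)), np.ones(1))


class TestFitClogit:
    def test_parameter_recovery_within_3se(self, clogit_dataset, schema):
        fit = r.fit_clogit(clogit_dataset, schema)
        assert fit.converged
        z = (fit.coefficients - REFERENCE_MIXL_MEANS) / fit.se
        assert np.all(np.abs(z) < 3)

    def test_covariance_symmetric_psd(self, clogit_dataset, schema):
        fit = r.fit_clogit(clogit_dataset, schema)
        cov = fit.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        np.testing.assert_allclose(fit.se.to_numpy(), np.sqrt(np.diag(cov)))

    def test_random_choices_give_null_model(self, schema, paper_design):
        design, _ = paper_design
        dgp = r.DataGeneratingProcess(kind="clogit", mean=REFERENCE_MIXL_MEANS * 0.0)
        dataset, _, _ = r.simulate_study(
            dgp, design, schema, n_respondents=352, seed=21, with_covariates=False
        )
        fit = r.fit_clogit(dataset, schema)
        assert np.all(np.abs(fit.z) < 4)
        assert fit.loglik == pytest.approx(5632 * np.log(0.5), rel=0.01)

    def test_separable_data_flagged_not_raised(self, toy_schema):
        # alternative with "hi"/"on" always chosen -> infinite MLE
        rows = []
        for i in range(20):
            rows.append((i, 0, "A", 1, "hi", "on"))
            rows.append((i, 0, "B", 0, "lo", "off"))
        df = pd.DataFrame(
            rows, columns=["respondent_id", "task_id", "alt", "chosen", "first", "second"]
        )
        fit = r.fit_clogit(r.ChoiceDataset(df, toy_schema), toy_schema)
        assert not fit.converged

    def test_scale_invariance_of_salary_units(self, clogit_dataset, schema):
        fit_etb = r.fit_clogit(clogit_dataset, schema)
        # same salary attribute measured in thousands of ETB
        k_attrs = tuple(
            Attribute(
                a.name,
                a.levels,
                coding=a.coding,
                reference=a.reference,
                numeric_values=(
                    {lv: v / 1000.0 for lv, v in a.numeric_values.items()}
                    if a.coding == "linear"
                    else None
                ),
            )
            for a in schema.attributes
        )
        fit_kilo = r.fit_clogit(clogit_dataset, AttributeSchema(k_attrs))
        assert fit_kilo.loglik == pytest.approx(fit_etb.loglik, abs=1e-8)
        assert fit_kilo.coefficients["salary"] == pytest.approx(
            1000.0 * fit_etb.coefficients["salary"], rel=1e-6
        )

    def test_matches_statsmodels_reference(self, clogit_dataset, schema):
        # for paired tasks the conditional logit is a binary logit on the
        # encoded differences without intercept: independent implementation
        import statsmodels.api as sm

        dx, y, _ = r.paired_differences(clogit_dataset, schema)
        ref = sm.Logit(y, dx).fit(disp=0, method="newton", tol=1e-10)
        ours = r.fit_clogit(clogit_dataset, schema)
        np.testing.assert_allclose(
            ours.coefficients.to_numpy(), ref.params, rtol=0, atol=1e-4
        )
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_recovery_rmse_shrinks_with_sample_size(self, schema, paper_design):
        design, _ = paper_design
        truth = REFERENCE_MIXL_MEANS
        scale = np.array([1e4, 1, 1, 1, 1, 1])  # salary on comparable footing
        rmse = {}
        for n in (352, 4000):
            errs = []
            for seed in (31, 32):
                ds, _, _ = r.simulate_study(
                    r.reference_clogit_dgp(), design, schema, n, seed=seed,
                    with_covariates=False,
                )
                fit = r.fit_clogit(ds, schema)
                errs.append(((fit.coefficients - truth).to_numpy() * scale) ** 2)
            rmse[n] = float(np.sqrt(np.mean(errs)))
        assert rmse[4000] < rmse[352]


class TestHalton:
    def test_base2_prefix(self):
        np.testing.assert_allclose(halton_sequence(2, 3), [0.5, 0.25, 0.75])

    def test_base3_prefix(self):
        np.testing.assert_allclose(halton_sequence(3, 3), [1 / 3, 2 / 3, 1 / 9])

    def test_values_in_unit_interval_and_deterministic(self):
        a = halton_sequence(7, 500, burn=50)
        b = halton_sequence(7, 500, burn=50)
        assert np.all((a > 0) & (a < 1))
        np.testing.assert_array_equal(a, b)

    def test_burn_discards_prefix(self):
        full = halton_sequence(2, 10)
        np.testing.assert_allclose(halton_sequence(2, 7, burn=3), full[3:])

    @pytest.mark.parametrize("base", [4, 1, 9])
    def test_nonprime_base_rejected(self, base):
        with pytest.raises(ValueError, match="prime"):
            halton_sequence(base, 5)

    def test_normal_draws_shape_and_partition(self):
        z = halton_normal_draws(4, 10, 3, burn=50)
        assert z.shape == (4, 10, 3)
        # respondent partitioning: respondents take consecutive stretches
        flat = halton_normal_draws(1, 40, 3, burn=50)
        np.testing.assert_allclose(z.reshape(40, 3), flat.reshape(40, 3))

    def test_scrambled_draws_seeded(self):
        a = halton_normal_draws(2, 5, 2, scramble=True, seed=3)
        b = halton_normal_draws(2, 5, 2, scramble=True, seed=3)
        c = halton_normal_draws(2, 5, 2, scramble=True, seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)


class TestMixlLoglik:
    def _panel(self, dataset, schema):
        dx, y, resp = r.paired_differences(dataset, schema)
        order, uniq, starts, inverse = _panel_index(resp)
        return dx[order], y[order], starts, inverse, len(uniq)

    def test_zero_sds_equals_clogit(self, mixl_dataset, schema):
        dx, y, starts, inverse, n = self._panel(mixl_dataset, schema)
        beta = np.array([2e-4, 0.3, 1.0, 0.5, 0.4, 0.45])
        z = halton_normal_draws(n, 20, 5)
        sll, _, _ = mixl_simulated_loglik(
            beta, np.zeros(5), dx, y, inverse, starts, z, np.arange(1, 6)
        )
        ll, _, _ = clogit_loglik(beta, dx, y)
        assert sll == pytest.approx(ll, abs=1e-10)

    def test_matches_brute_force_monte_carlo(self, mixl_dataset, schema):
        # 5-respondent panel; independent pseudo-random oracle at R=200,000
        dx, y, starts, inverse, n = self._panel(mixl_dataset, schema)
        keep = starts[5]
        dx5, y5 = dx[:keep], y[:keep]
        inv5, starts5 = inverse[:keep], starts[:5]
        means = np.array([2.4e-4, 0.28, 1.0, 0.47, 0.44, 0.45])
        sds = np.array([0.65, 1.1, 0.98, 0.74, 0.3])
        ridx = np.arange(1, 6)
        z = halton_normal_draws(5, 2000, 5)
        sll, _, _ = mixl_simulated_loglik(means, sds, dx5, y5, inv5, starts5, z, ridx)
        rng = np.random.default_rng(12345)
        zbig = rng.standard_normal((5, 200_000, 5))
        oracle, _, _ = mixl_simulated_loglik(means, sds, dx5, y5, inv5, starts5, zbig, ridx)
        assert sll == pytest.approx(oracle, abs=0.2)

    def test_gradient_matches_finite_differences(self, mixl_dataset, schema):
        dx, y, starts, inverse, n = self._panel(mixl_dataset, schema)
        keep = starts[10]
        dxn = dx[:keep] / dx.std(axis=0)
        y10, inv10, starts10 = y[:keep], inverse[:keep], starts[:10]
        z = halton_normal_draws(10, 50, 5)
        ridx = np.arange(1, 6)
        theta = np.concatenate([np.full(6, 0.3), np.full(5, 0.4)])

        def sll_at(t):
            s, gm, gs = mixl_simulated_loglik(
                t[:6], t[6:], dxn, y10, inv10, starts10, z, ridx
            )
            return s, np.concatenate([gm, gs])

        s0, g0 = sll_at(theta)
        eps = 1e-6
        for k in range(len(theta)):
            e = np.zeros_like(theta)
            e[k] = eps
            sp, _ = sll_at(theta + e)
            sm_, _ = sll_at(theta - e)
            assert g0[k] == pytest.approx((sp - sm_) / (2 * eps), rel=1e-4, abs=1e-4)

    def test_truth_beats_perturbation(self, mixl_dataset, schema):
        dx, y, starts, inverse, n = self._panel(mixl_dataset, schema)
        z = halton_normal_draws(n, 100, 5)
        ridx = np.arange(1, 6)
        truth_m = REFERENCE_MIXL_MEANS.to_numpy()
        truth_s = REFERENCE_MIXL_SDS.to_numpy()[1:]
        s_true, _, _ = mixl_simulated_loglik(truth_m, truth_s, dx, y, inverse, starts, z, ridx)
        s_pert, _, _ = mixl_simulated_loglik(
            truth_m * 0.3, truth_s + 1.0, dx, y, inverse, starts, z, ridx
        )
        assert s_true > s_pert

    def test_zero_draws_rejected(self, mixl_dataset, schema):
        dx, y, starts, inverse, n = self._panel(mixl_dataset, schema)
        with pytest.raises(ValueError):
            mixl_simulated_loglik(
                np.zeros(6), np.zeros(5), dx, y, inverse, starts,
                np.empty((n, 0, 5)), np.arange(1, 6),
            )


class TestFitMixl:
    def test_study_scale_recovery_within_3se(self, mixl_fit):
        assert mixl_fit.converged
        z_means = (mixl_fit.means - REFERENCE_MIXL_MEANS) / mixl_fit.se_means
        assert np.all(np.abs(z_means) < 3)
        truth_sds = REFERENCE_MIXL_SDS[list(mixl_fit.sds.index)]
        z_sds = (mixl_fit.sds - truth_sds) / mixl_fit.se_sds
        assert np.all(np.abs(z_sds) < 3)

    def test_salary_fixed_by_default(self, mixl_fit):
        assert "salary" not in mixl_fit.sds.index
        assert mixl_fit.random == tuple(c for c in mixl_fit.means.index if c != "salary")

    def test_zero_sd_attribute_estimated_insignificant(self, mixl_fit):
        # workload's true SD is 0.01: its estimate should not be significant
        z = mixl_fit.sds["workload_normal"] / mixl_fit.se_sds["workload_normal"]
        assert abs(z) < 1.96

    def test_reported_sds_nonnegative(self, mixl_fit):
        assert np.all(mixl_fit.sds.to_numpy() >= 0)

    def test_doubling_draws_stable_loglik(self, mixl_dataset, schema, mixl_fit):
        dx, y, resp = r.paired_differences(mixl_dataset, schema)
        order, uniq, starts, inverse = _panel_index(resp)
        dx, y = dx[order], y[order]
        ridx = np.array([1, 2, 3, 4, 5])
        means = mixl_fit.means.to_numpy()
        sds = mixl_fit.sds.to_numpy()
        lls = []
        for R in (200, 400):
            z = halton_normal_draws(len(uniq), R, 5)
            sll, _, _ = mixl_simulated_loglik(means, sds, dx, y, inverse, starts, z, ridx)
            lls.append(sll)
        assert abs(lls[1] - lls[0]) < 0.005 * abs(lls[0])


class TestLatentClass:
    def test_single_class_equals_clogit(self, clogit_dataset, schema):
        lcm = r.fit_lcm(clogit_dataset, schema, C=1)
        cl = r.fit_clogit(clogit_dataset, schema)
        assert lcm.loglik == pytest.approx(cl.loglik, abs=1e-6)
        np.testing.assert_allclose(
            lcm.class_coefs["class_1"].to_numpy(), cl.coefficients.to_numpy(), atol=1e-8
        )

    def test_em_loglik_nondecreasing(self, lcm_dataset, schema):
        dataset, _ = lcm_dataset
        fit = r.fit_lcm(dataset, schema, C=3, n_starts=1, seed=11)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)

    def test_three_class_share_recovery(self, lcm_dataset, schema):
        dataset, classes = lcm_dataset
        fit = r.fit_lcm(dataset, schema, C=3, n_starts=3, seed=11)
        # labels sorted by descending salary coefficient; compare as sets
        est = np.sort(fit.shares)
        true_draw = np.sort(np.bincount(classes, minlength=3) / len(classes))
        np.testing.assert_allclose(est, true_draw, atol=0.05)
        np.testing.assert_allclose(est, np.sort(REFERENCE_LCM_SHARES), atol=0.06)

    def test_posterior_rows_sum_to_one(self, lcm_dataset, schema):
        dataset, _ = lcm_dataset
        fit = r.fit_lcm(dataset, schema, C=2, n_starts=1, seed=2)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(fit.shares > 0) and fit.shares.sum() == pytest.approx(1.0)

    def test_aic_formula(self, lcm_selection):
        table, _, fits = lcm_selection
        for _, row in table.iterrows():
            C = int(row["C"])
            k = C * 6 + (C - 1)
            assert row["aic"] == pytest.approx(2 * k - 2 * row["loglik"], abs=1e-8)

    def test_aic_selects_three_classes(self, lcm_selection):
        _, chosen, _ = lcm_selection
        assert chosen == 3

    def test_homogeneous_data_selects_one_class(self, clogit_dataset, schema):
        _, chosen, _ = r.select_classes(
            clogit_dataset, schema, C_range=(1, 2), seed=4, n_starts=2
        )
        assert chosen == 1


class TestInteractions:
    def test_empty_spec_equals_clogit(self, clogit_dataset, schema):
        inter = r.fit_interactions(clogit_dataset, schema, ())
        cl = r.fit_clogit(clogit_dataset, schema)
        np.testing.assert_allclose(
            inter.base.to_numpy(), cl.coefficients.to_numpy(), atol=1e-10
        )
        assert inter.loglik == pytest.approx(cl.loglik, abs=1e-8)

    def test_young_service_interaction_recovered(self, schema, paper_design):
        design, _ = paper_design
        dgp = r.reference_clogit_dgp()
        dgp.interactions = (("service_oneyear", "young", 0.5),)
        dataset, _, _ = r.simulate_study(dgp, design, schema, 2000, seed=13)
        fit = r.fit_interactions(dataset, schema, (("service_oneyear", "young"),))
        wald = fit.wald()
        row = wald.loc["service_oneyear_x_young"]
        assert abs(row["z"]) > 1.96
        assert row["coef"] == pytest.approx(0.5, abs=3 * row["se"])

    def test_no_sex_effect_type_i_error(self, schema, paper_design):
        # under a DGP without sex effects the male interaction should be
        # rejected at 5% only at about the nominal rate
        design, _ = paper_design
        rejections = 0
        for seed in range(40, 60):
            dataset, _, _ = r.simulate_study(
                r.reference_clogit_dgp(), design, schema, 352, seed=seed
            )
            fit = r.fit_interactions(dataset, schema, (("drug_supply_adequate", "male"),))
            if fit.wald().loc["drug_supply_adequate_x_male", "p"] < 0.05:
                rejections += 1
        assert rejections <= 3  # P(X > 3 | Binomial(20, 0.05)) < 0.02

    def test_collinear_interactions_rejected(self, clogit_dataset, schema):
        spec = (("service_oneyear", "young"), ("service_oneyear", "young"))
        with pytest.raises(ValueError, match="service_oneyear_x_young"):
            r.fit_interactions(clogit_dataset, schema, spec)
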