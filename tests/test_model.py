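import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

from epolr import (
    CohortConfig,
    CohortTable,
    OrdinalScale,
    TransformationSpec,
    fit,
    generate_cohort,
    likelihood_contribution,
    log_likelihood,
    predict_distribution,
    wald_inference,
)
from epolr.model import WaldSummary


@pytest.fixture(scope="module")
def toy_spec():
    return TransformationSpec(scale=OrdinalScale(6), strata_levels=("all",),
                              n_params=4, baseline_varying=False)


@pytest.fixture(scope="module")
def toy_theta(toy_spec):
    return np.linspace(-2.0, 2.0, toy_spec.n_theta)


class TestLikelihoodContribution:
    def test_pmf_telescopes_to_one(self, toy_spec, toy_theta):
        for beta, x in [(0.0, 0), (0.7, 1), (-1.2, 1)]:
            total = sum(
                likelihood_contribution(y, 0.0, "all", x, toy_theta, beta,
                                        toy_spec)
                for y in range(7))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_boundary_categories(self, toy_spec, toy_theta):
        from epolr.transform import eval_h
        h0 = eval_h(0, "all", 0.0, toy_theta, toy_spec)
        p0 = likelihood_contribution(0, 0.0, "all", 1, toy_theta, 0.5,
                                     toy_spec)
        assert p0 == pytest.approx(expit(h0 + 0.5), rel=1e-12)
        h5 = eval_h(5, "all", 0.0, toy_theta, toy_spec)
        p6 = likelihood_contribution(6, 0.0, "all", 1, toy_theta, 0.5,
                                     toy_spec)
        assert p6 == pytest.approx(1 - expit(h5 + 0.5), rel=1e-12)

    def test_nonfinite_parameters_raise(self, toy_spec, toy_theta):
        with pytest.raises(ValueError):
            likelihood_contribution(2, 0.0, "all", 0, toy_theta, np.nan,
                                    toy_spec)


class TestLogLikelihood:
    def test_row_duplication_doubles(self, small_trial, small_spec):
        theta = np.repeat(np.linspace(-1, 1, small_spec.n_params),
                          small_spec.n_strata * small_spec.n_covariates)
        ll1 = log_likelihood(small_trial, theta, 0.3, small_spec)
        doubled = CohortTable(
            baseline=np.tile(small_trial.baseline, 2),
            outcome=np.tile(small_trial.outcome, 2),
            stratum=np.tile(small_trial.stratum, 2),
            arm=np.tile(small_trial.arm, 2))
        assert log_likelihood(doubled, theta, 0.3, small_spec) == \
            pytest.approx(2 * ll1, rel=1e-12)
        assert ll1 <= 0

    def test_binary_outcome_matches_logistic_loglik(self, binary_cohort):
        table, spec = binary_cohort
        # theta flat (P=2, S=1, C=1): only theta[0] = h(0) enters
        h0, beta = -0.4, 0.9
        theta = np.array([h0, h0 + 1.0])
        eta = h0 + beta * table.arm
        expected = np.sum(np.where(table.outcome == 0,
                                   np.log(expit(eta)),
                                   np.log(1 - expit(eta))))
        assert log_likelihood(table, theta, beta, spec) == \
            pytest.approx(expected, rel=1e-10)


class TestFit:
    def test_binary_reduction_equals_logistic_regression(self, binary_cohort):
        table, spec = binary_cohort
        f = fit(table, spec)
        X = sm.add_constant(table.arm.astype(float))
        ref = sm.Logit((table.outcome == 0).astype(int), X).fit(disp=0)
        assert f.beta_hat == pytest.approx(ref.params[1], abs=1e-6)
        assert f.beta_se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_null_fit_is_nested(self, selfcare_cohort, selfcare_null_fit):
        table, truth = selfcare_cohort
        null = selfcare_null_fit
        alt = fit(table, truth["spec"])
        assert null.beta_hat == 0.0
        assert null.loglik <= alt.loglik + 1e-6

    def test_row_order_invariance(self, selfcare_cohort):
        table, truth = selfcare_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        shuffled = CohortTable(table.baseline[perm], table.outcome[perm],
                               table.stratum[perm], table.arm[perm])
        f1 = fit(table, truth["spec"])
        f2 = fit(shuffled, truth["spec"])
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f2.beta_hat == pytest.approx(f1.beta_hat, abs=1e-5)

    def test_stratum_relabeling_invariance(self):
        table, truth = generate_cohort(CohortConfig(
            preset="scim_selfcare", n_subjects=250, seed=9, stratified=True,
            order=4))
        spec = truth["spec"]
        f1 = fit(table, spec)
        renamed = {s: f"grp-{i}" for i, s in enumerate(spec.strata_levels)}
        table2 = CohortTable(table.baseline, table.outcome,
                             np.array([renamed[s] for s in table.stratum],
                                      dtype=object), table.arm)
        spec2 = TransformationSpec(
            scale=spec.scale,
            strata_levels=tuple(renamed[s] for s in spec.strata_levels),
            n_params=spec.n_params, baseline_varying=True,
            baseline_range=spec.baseline_range)
        f2 = fit(table2, spec2)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f2.beta_hat == pytest.approx(f1.beta_hat, abs=1e-5)

    def test_unidentifiable_stratum_raises(self, toy_spec):
        table = CohortTable(baseline=np.zeros(10),
                            outcome=np.full(10, 3),
                            stratum=np.array(["all"] * 10, dtype=object),
                            arm=np.array([0, 1] * 5))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit(table, toy_spec)

    def test_recovery_within_three_se(self):
        beta_true = np.log(2)
        table, truth = generate_cohort(CohortConfig(
            preset="scim_selfcare", n_subjects=2000, seed=31,
            beta_benefit=beta_true))
        f = fit(table, truth["spec"])
        assert f.converged
        assert abs(-f.beta_hat - beta_true) < 3 * f.beta_se


class TestPrediction:
    def test_pmf_normalized_and_ordered(self, selfcare_cohort):
        table, truth = selfcare_cohort
        f = fit(table, truth["spec"])
        rng = np.random.default_rng(1)
        for _ in range(20):
            b = rng.integers(0, 21)
            p0 = predict_distribution(f, b, "all", 0)
            p1 = predict_distribution(f, b, "all", 1)
            assert p0.sum() == pytest.approx(1.0, abs=1e-10)
            assert p1.sum() == pytest.approx(1.0, abs=1e-10)
            cdf0, cdf1 = np.cumsum(p0), np.cumsum(p1)
            if f.beta_hat > 0:
                assert np.all(cdf1 >= cdf0 - 1e-12)
            else:
                assert np.all(cdf1 <= cdf0 + 1e-12)

    def test_proportional_odds_shift_is_constant(self, selfcare_cohort):
        table, truth = selfcare_cohort
        f = fit(table, truth["spec"])
        p0 = predict_distribution(f, 8, "all", 0)
        p1 = predict_distribution(f, 8, "all", 1)
        cdf0, cdf1 = np.cumsum(p0)[:-1], np.cumsum(p1)[:-1]
        shifts = logit(cdf1) - logit(cdf0)
        np.testing.assert_allclose(shifts, f.beta_hat, atol=1e-8)

    def test_unseen_stratum_raises(self, selfcare_cohort):
        table, truth = selfcare_cohort
        f = fit(table, truth["spec"])
        with pytest.raises(KeyError):
            predict_distribution(f, 8, "elsewhere", 0)


class TestWald:
    def test_log_symmetric_interval(self, selfcare_cohort):
        table, truth = selfcare_cohort
        f = fit(table, truth["spec"])
        w = wald_inference(f)
        assert w.or_lte_ci[0] * w.or_lte_ci[1] == \
            pytest.approx(w.or_lte ** 2, rel=1e-10)
        assert w.or_benefit == pytest.approx(1 / w.or_lte, rel=1e-12)

    def test_normal_tail_oracle(self):
        # beta=0.5, se=0.1 -> z=5, p = 2 Phi(-5)
        from epolr.model import EPolrFit
        spec = TransformationSpec(scale=OrdinalScale(5),
                                  strata_levels=("all",), n_params=3,
                                  baseline_varying=False)
        f = EPolrFit(beta_hat=0.5, theta_hat=np.zeros(3), loglik=-1.0,
                     converged=True, spec=spec, n_obs=10,
                     include_treatment=True, beta_se=0.1)
        w = wald_inference(f)
        assert w.z == pytest.approx(5.0)
        assert w.p_value == pytest.approx(2 * norm.sf(5), rel=1e-10)

    def test_serializes(self, selfcare_cohort):
        import json
        table, truth = selfcare_cohort
        w = wald_inference(fit(table, truth["spec"]))
        assert isinstance(w, WaldSummary)
        json.dumps(w.to_dict())
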