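"""Likelihood, Metropolis transition rule, and family-fit behaviour."""

import math

import numpy as np
import pytest

import imksurv as ik
from imksurv.bayes import PARAM_NAMES, FamilyLikelihood, metropolis_acceptance

SAS_TRUTH = ik.SAS_FAMILY.as_dict()


def theta_from(d):
    return ik.ParameterVector(**{n: d[n] for n in PARAM_NAMES})


@pytest.fixture(scope="module")
def acute_bundle(ctx=ik.REFERENCE_CONTEXT):
    return ik.simulate_family_bundle(ik.SAS_FAMILY, ctx, seed=0)


class TestLogLikelihood:
    def test_zero_residual_single_record(self, ctx):
        # one observation matching the model exactly: density 1/(0.1 sqrt(2 pi))
        model = ik.SAS_FAMILY.parent_model()
        S = model.survival(ctx, 2.0)
        data = ik.SurvivalDataset.from_observations("SAS", [2.0], [-np.log(S)])
        ll = ik.log_likelihood(
            data, theta_from(SAS_TRUTH), ik.LikelihoodConfig(sigma=0.1), ctx
        )
        assert ll == pytest.approx(math.log(3.98942), abs=1e-5)

    def test_stem_above_progeny_rejected_as_zero_density(self, ctx):
        data = ik.SurvivalDataset.from_observations("SAS", [2.0], [0.5])
        bad = dict(SAS_TRUTH, alpha0s=0.5)  # above alpha0p = 0.208
        assert ik.log_likelihood(
            data, theta_from(bad), ik.LikelihoodConfig(sigma=0.1), ctx
        ) == -np.inf

    def test_doubling_sigma_at_zero_residual_costs_n_log_two(self, ctx):
        model = ik.SAS_FAMILY.parent_model()
        doses = [1.0, 2.0, 4.0, 8.0]
        obs = [-np.log(model.survival(ctx, d)) for d in doses]
        data = ik.SurvivalDataset.from_observations("SAS", doses, obs)
        ll1 = ik.log_likelihood(data, theta_from(SAS_TRUTH), ik.LikelihoodConfig(0.1), ctx)
        ll2 = ik.log_likelihood(data, theta_from(SAS_TRUTH), ik.LikelihoodConfig(0.2), ctx)
        assert ll1 - ll2 == pytest.approx(len(doses) * math.log(2.0), abs=1e-10)

    def test_resistant_line_uses_derived_progeny(self, ctx):
        # the resistant flag must change predictions via the w_SLDR scaling
        doses = [2.0, 6.0, 10.0]
        lik = FamilyLikelihood(
            ik.SurvivalDataset.from_observations("SAS", doses, [0.0] * 3),
            ik.SurvivalDataset.from_observations("SAS-R", doses, [0.0] * 3),
            ctx,
        )
        parent_pred, resistant_pred = lik.predicted(theta_from(SAS_TRUTH).to_array())
        parent_model = ik.SAS_FAMILY.parent_model()
        resistant_model = ik.SAS_FAMILY.resistant_model()
        for d, yp, yr in zip(doses, parent_pred, resistant_pred):
            assert yp == pytest.approx(-math.log(parent_model.survival(ctx, d)), rel=1e-12)
            assert yr == pytest.approx(-math.log(resistant_model.survival(ctx, d)), rel=1e-12)


class TestTransitionRule:
    def test_equal_posteriors_always_accepted(self):
        assert metropolis_acceptance(-3.0, -3.0) == 1.0

    def test_half_probability_for_log_two_deficit(self):
        assert metropolis_acceptance(-1.0 - math.log(2), -1.0) == pytest.approx(0.5)

    def test_constraint_violating_candidate_never_accepted(self):
        assert metropolis_acceptance(-np.inf, -1.0) == 0.0
        assert metropolis_acceptance(-np.inf, -np.inf) == 0.0

    def test_uphill_moves_always_accepted(self):
        assert metropolis_acceptance(5.0, -1.0) == 1.0


class TestRSquared:
    def test_perfect_prediction(self):
        assert ik.r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert ik.r_squared([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert ik.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ik.r_squared([2, 2, 2], [1, 2, 3])


class TestSamplerCorrectness:
    def test_prior_only_parameter_samples_its_gaussian(self, ctx):
        # acute survival is independent of (a+c)_p, so with everything else
        # pinned the repair-rate posterior must reproduce its normal prior;
        # checks the Metropolis kernel against a closed-form target
        fixed = tuple(
            (n, SAS_TRUTH[n]) for n in PARAM_NAMES if n != "repair_p"
        )
        priors = ik.PriorSpec(repair_prior=(1.5, 0.3), fixed=fixed)
        data = ik.simulate_survival_dataset(
            ik.SAS_FAMILY.parent_model(), ctx, ik.ExperimentDesign(sigma=0.1), seed=1,
            cell_line="SAS",
        )
        fit = ik.fit_family(
            data, None, priors, ctx,
            likelihood=ik.LikelihoodConfig(sigma=0.1),
            config=ik.SamplerConfig(n_iter=40000), seed=42,
        )
        mean = fit.summary.table.loc["repair_p", "mean"]
        sd = fit.summary.table.loc["repair_p", "sd"]
        ess = max(float(fit.summary.ess["repair_p"]), 4.0)
        mc_se = sd / math.sqrt(ess)
        assert mean == pytest.approx(1.5, abs=3 * mc_se)
        assert sd == pytest.approx(0.3, rel=0.15)

    def test_point_mass_priors_return_truth(self, ctx, acute_bundle):
        fixed = tuple((n, SAS_TRUTH[n]) for n in PARAM_NAMES)
        priors = ik.PriorSpec(fixed=fixed)
        fit = ik.fit_family(
            acute_bundle.parent_survival, acute_bundle.resistant_survival,
            priors, ctx, likelihood=ik.LikelihoodConfig(sigma=0.1),
            config=ik.SamplerConfig(n_iter=2000), seed=3,
        )
        for n in PARAM_NAMES:
            assert fit.summary.table.loc[n, "mean"] == pytest.approx(SAS_TRUTH[n])
            assert fit.summary.table.loc[n, "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_repair_tie_holds_in_every_sample(self, ctx, acute_bundle):
        priors = ik.PriorSpec(
            repair_prior=(1.3, 0.4),
            f_s_parent_prior=(0.012, 0.006),
            f_s_resistant_prior=(0.083, 0.04),
        )
        fit = ik.fit_family(
            acute_bundle.parent_survival, acute_bundle.resistant_survival,
            priors, ctx, config=ik.SamplerConfig(n_iter=4000), seed=7,
        )
        np.testing.assert_allclose(
            fit.chain["repair_H"],
            fit.chain["w_sldr"] * fit.chain["repair_p"],
            rtol=1e-12,
        )

    def test_same_seed_reproduces_chain_exactly(self, ctx, acute_bundle):
        priors = ik.PriorSpec(
            repair_prior=(1.3, 0.4),
            f_s_parent_prior=(0.012, 0.006),
            f_s_resistant_prior=(0.083, 0.04),
        )
        kwargs = dict(
            parent_data=acute_bundle.parent_survival,
            resistant_data=acute_bundle.resistant_survival,
            priors=priors, ctx=ctx, config=ik.SamplerConfig(n_iter=3000), seed=11,
        )
        fit1 = ik.fit_family(**kwargs)
        fit2 = ik.fit_family(**kwargs)
        assert fit1.chain.equals(fit2.chain)

    def test_w_sldr_unidentified_without_resistant_line(self, ctx, acute_bundle):
        # without resistant-line curves the posterior of w_SLDR stays at its
        # uniform prior over [1, 5] (acute parent data carries no information)
        priors = ik.PriorSpec(
            repair_prior=(1.3, 0.4),
            f_s_parent_prior=(0.012, 0.006),
            f_s_resistant_prior=(0.083, 0.04),
        )
        fit = ik.fit_family(
            acute_bundle.parent_survival, None, priors, ctx,
            likelihood=ik.LikelihoodConfig(sigma=0.1),
            config=ik.SamplerConfig(n_iter=40000), seed=5,
        )
        w = fit.chain["w_sldr"]
        ess = max(float(fit.summary.ess["w_sldr"]), 4.0)
        mc_se = w.std() / math.sqrt(ess)
        assert w.mean() == pytest.approx(3.0, abs=4 * mc_se)
        assert w.std() == pytest.approx(4.0 / math.sqrt(12.0), rel=0.25)

    def test_two_seeds_agree_within_monte_carlo_error(self, ctx, acute_bundle):
        priors = ik.PriorSpec(
            repair_prior=(1.3, 0.4),
            f_s_parent_prior=(0.012, 0.006),
            f_s_resistant_prior=(0.083, 0.04),
        )
        kwargs = dict(
            parent_data=acute_bundle.parent_survival,
            resistant_data=acute_bundle.resistant_survival,
            priors=priors, ctx=ctx, config=ik.SamplerConfig(n_iter=30000),
        )
        fit_a = ik.fit_family(seed=101, **kwargs)
        fit_b = ik.fit_family(seed=202, **kwargs)
        for n in ("alpha0p", "beta0p", "w_sldr", "f_s_resistant"):
            se_a = fit_a.summary.table.loc[n, "sd"] / math.sqrt(
                max(float(fit_a.summary.ess[n]), 4.0)
            )
            se_b = fit_b.summary.table.loc[n, "sd"] / math.sqrt(
                max(float(fit_b.summary.ess[n]), 4.0)
            )
            diff = abs(
                fit_a.summary.table.loc[n, "mean"] - fit_b.summary.table.loc[n, "mean"]
            )
            assert diff < 3.0 * math.hypot(se_a, se_b)
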