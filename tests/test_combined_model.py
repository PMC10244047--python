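"""Combined trial-plus-cohort model: mixture identity, conjugate eligibility
posterior, prior dominance, bias identification and reduction to the
cohort-only model."""

import numpy as np
import pytest

from emrsynth import (
    InformativePrior,
    MCMCConfig,
    ScenarioConfig,
    fit_cohort_model,
    fit_combined_model,
    mixture_effect,
    simulate_cohort,
)
from emrsynth.combined_model import CombinedTrajectoryModel


class TestMixtureEffect:
    def test_degenerate_mixture(self):
        c = np.full(10, 0.7)
        pi = np.linspace(0.1, 0.9, 10)
        np.testing.assert_allclose(mixture_effect(c, c, pi), c)

    def test_pi_one_returns_eligible_effect(self):
        a1, a2 = np.array([1.5, 2.0]), np.array([0.5, 0.0])
        np.testing.assert_allclose(
            mixture_effect(a1, a2, np.ones(2)), a1
        )

    def test_even_mixture(self):
        out = mixture_effect(np.array([1.5]), np.array([0.5]), np.array([0.5]))
        assert out[0] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixture_effect(np.ones(3), np.ones(2), np.ones(3))


@pytest.fixture(scope="module")
def biased_quiet_cohort():
    """Low-noise cohort with both biases on: projection bias 0.5 (untreated
    post-offer slope 0 vs pre-offer -2 at alpha 0.25) and eligible effect
    1.5 vs population effect 1 at pi = 0.5 (so ARE2 = 0.5)."""
    sc = ScenarioConfig(
        n2=100, pi=0.5, ARE1=1.5, gamma2=0.0, sigma=0.3, sigma0=2.0,
        nu_sq=0.02, tau1_sq=0.01, tau0_sq=0.01, obs_per_subject=(5, 8),
    )
    return sc, simulate_cohort(sc, np.random.default_rng(31))


class TestGuards:
    def test_single_stratum_rejected_by_default(self):
        sc = ScenarioConfig(n2=30, pi=1 - 1e-12)
        cohort = simulate_cohort(sc, np.random.default_rng(0))
        with pytest.raises(ValueError, match="strata"):
            fit_combined_model(cohort, sc.alpha, InformativePrior(1.0, 0.3))

    def test_zero_prior_sd_rejected(self, biased_quiet_cohort):
        sc, cohort = biased_quiet_cohort
        with pytest.raises(ValueError):
            fit_combined_model(cohort, sc.alpha, InformativePrior(1.0, 0.0))

    def test_missing_eligibility_flags_rejected(self, biased_quiet_cohort):
        sc, cohort = biased_quiet_cohort
        stripped = type(cohort)(cohort.records, cohort.baselines, eligible={})
        with pytest.raises(ValueError, match="eligibility"):
            fit_combined_model(stripped, sc.alpha, InformativePrior(1.0, 0.3))


@pytest.fixture(scope="module")
def fitted(biased_quiet_cohort):
    sc, cohort = biased_quiet_cohort
    # near point-mass prior at the true eligible-stratum effect
    prior = InformativePrior(mean=1.5, sd=1e-3)
    res = fit_combined_model(
        cohort, sc.alpha, prior, re_spec=("b0", "b1"),
        mcmc_config=MCMCConfig(draws=1000, seed=31),
    )
    return sc, res


class TestPosterior:
    def test_point_mass_prior_identifies_projection_bias(self, fitted):
        """With ARE1 pinned, phi_alpha must center on the gap between the
        eligible-stratum extrapolation estimate and ARE1 (here 0.5)."""
        sc, res = fitted
        assert res.mean("phi_alpha") == pytest.approx(
            sc.phi_alpha, abs=3 * res.sd("phi_alpha") + 0.05
        )

    def test_point_mass_prior_identifies_non_eligible_effect(self, fitted):
        sc, res = fitted
        assert res.mean("ARE2") == pytest.approx(
            sc.ARE2, abs=3 * res.sd("ARE2") + 0.05
        )

    def test_prior_dominance_limit(self, fitted):
        """As the ARE1 prior sd shrinks the posterior collapses onto the
        prior mean."""
        _, res = fitted
        assert res.mean("ARE1") == pytest.approx(1.5, abs=0.01)
        assert res.sd("ARE1") <= 2e-3

    def test_mixture_identity_holds_per_draw(self, fitted):
        _, res = fitted
        lhs = res.draws["ARE"]
        rhs = res.draws["pi"] * res.draws["ARE1"] + (
            1.0 - res.draws["pi"]
        ) * res.draws["ARE2"]
        np.testing.assert_array_equal(lhs, rhs)

    def test_pi_posterior_is_beta_binomial(self):
        """With a U(0,1) prior and s of n subjects eligible the posterior of
        pi is Beta(s+1, n-s+1); 70 of 100 eligible gives mean 71/102."""
        sc = ScenarioConfig(n2=100, pi=0.7, sigma=0.5, obs_per_subject=(2, 4))
        rng = np.random.default_rng(17)
        cohort = simulate_cohort(sc, rng)
        # force exactly 70 eligible subjects
        ids = sorted(cohort.eligible)
        cohort.eligible = {s: i < 70 for i, s in enumerate(ids)}
        cohort.baselines["eligible"] = [cohort.eligible[s] for s in cohort.baselines.subject_id]
        res = fit_combined_model(
            cohort, sc.alpha, InformativePrior(1.0, 0.5),
            mcmc_config=MCMCConfig(draws=400, seed=17),
        )
        n_draws = res.flat("pi").size
        beta_sd = np.sqrt(71 * 31 / (102**2 * 103))
        assert res.mean("pi") == pytest.approx(
            71 / 102, abs=4 * beta_sd / np.sqrt(n_draws) + 1e-3
        )

    def test_single_phi_shared_by_both_strata(self, biased_quiet_cohort):
        """The projection bias enters the design once, unstratified."""
        sc, cohort = biased_quiet_cohort
        model = CombinedTrajectoryModel(
            cohort, sc.alpha, InformativePrior(1.5, 0.3)
        )
        X, _ = model.design(0.3)
        phi_col = X[:, 6]
        are_cols = X[:, 4] + X[:, 5]
        np.testing.assert_allclose(phi_col, are_cols)
        assert model.param_names.count("phi_alpha") == 1


def test_reduction_to_cohort_model_with_flat_prior():
    """With every subject eligible, an effectively flat ARE1 prior and the
    projection bias pinned at zero, the combined model's ARE1 posterior must
    match the cohort-only theta_alpha posterior on the same data."""
    sc = ScenarioConfig(
        n2=80, sigma=0.4, sigma0=2.0, nu_sq=0.05, tau1_sq=0.02,
        tau0_sq=0.01, obs_per_subject=(4, 8),
    )
    cohort = simulate_cohort(sc, np.random.default_rng(77))
    cohort.eligible = {s: True for s in cohort.eligible}

    cohort_res = fit_cohort_model(
        cohort, sc.alpha, re_spec=("b0", "b1"),
        mcmc_config=MCMCConfig(draws=1000, seed=7),
    )
    combined_res = fit_combined_model(
        cohort, sc.alpha, InformativePrior(0.0, 100.0),
        re_spec=("b0", "b1"),
        phi_prior_sd=1e-6,
        require_both_strata=False,
        mcmc_config=MCMCConfig(draws=1000, seed=7),
    )
    mc_tol = 3 * np.hypot(
        cohort_res.theta_alpha_se / np.sqrt(cohort_res.ess["theta_alpha"]),
        combined_res.sd("ARE1") / np.sqrt(combined_res.ess["ARE1"]),
    ) + 0.05
    assert combined_res.mean("ARE1") == pytest.approx(
        cohort_res.theta_alpha, abs=mc_tol
    )
    assert combined_res.mean("phi_alpha") == pytest.approx(0.0, abs=1e-4)
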