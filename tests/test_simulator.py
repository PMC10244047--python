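"""Generative-model contracts: exact effect at alpha, continuity, stratum
means, bias formulas, and bit-reproducibility."""

import numpy as np
import pandas as pd
import pytest

from emrsynth.meta_prior import summarize_trial
from emrsynth.simulator import (
    ScenarioConfig,
    SimulatedIndividual,
    biases,
    control_trajectory,
    simulate_cohort,
    simulate_study,
    simulate_trials,
    treated_trajectory,
    treatment_offset,
)


def noiseless(**kw):
    return ScenarioConfig(sigma=0.0, **kw)


def individual(delta_i=1.0, gamma0=20.0):
    return SimulatedIndividual(id="i", Z=1, Delta=delta_i, gamma0_i=gamma0)


class TestBiases:
    def test_projection_bias_from_slope_gap(self):
        sc = ScenarioConfig(gamma1=-2.0, gamma2=0.0, alpha=0.25)
        phi, _ = biases(sc)
        assert phi == pytest.approx(0.5)

    def test_generalizability_bias_from_stratum_gap(self):
        sc = ScenarioConfig(ARE1=0.5, ARE=1.0, pi=0.5)
        _, zeta = biases(sc)
        assert zeta == pytest.approx(-0.5)

    def test_equal_slopes_mean_no_projection_bias(self):
        for alpha in (0.25, 0.5, 1.0):
            sc = ScenarioConfig(gamma1=-2.0, gamma2=-2.0, alpha=alpha)
            assert biases(sc)[0] == 0.0

    def test_are2_solves_mixture_identity(self):
        sc = ScenarioConfig(ARE=1.0, ARE1=1.5, pi=0.5)
        assert sc.pi * sc.ARE1 + (1 - sc.pi) * sc.ARE2 == pytest.approx(sc.ARE)


class TestControlTrajectory:
    def test_value_at_offer_is_gamma0(self):
        sc = noiseless()
        assert control_trajectory(individual(), 0.0, sc) == pytest.approx(20.0)

    def test_straight_line_when_slopes_equal(self):
        sc = noiseless(gamma1=-2.0, gamma2=-2.0)
        diff = control_trajectory(individual(), 1.0, sc) - control_trajectory(
            individual(), -1.0, sc
        )
        assert diff == pytest.approx(-4.0)

    def test_flat_post_segment(self):
        sc = noiseless(gamma2=0.0)
        assert control_trajectory(individual(), 2.0, sc) == pytest.approx(20.0)


class TestTreatedTrajectory:
    @pytest.mark.parametrize("alpha,delta", [(0.25, 0.3), (1.0, 0.3), (0.5, 0.5)])
    def test_effect_at_alpha_is_exactly_delta_i(self, alpha, delta):
        sc = noiseless(alpha=alpha, delta=delta)
        ind = individual(delta_i=1.37)
        diff = treated_trajectory(ind, alpha, sc) - control_trajectory(ind, alpha, sc)
        assert diff == pytest.approx(1.37, abs=1e-12)

    def test_no_jump_at_offer(self):
        for alpha in (0.25, 1.0):
            sc = noiseless(alpha=alpha)
            assert treated_trajectory(individual(), 0.0, sc) == pytest.approx(20.0)

    def test_coincides_with_control_before_offer(self):
        sc = noiseless(alpha=1.0)
        ind = individual(delta_i=2.0)
        for t in (-1.0, -0.3, -1e-9):
            assert treated_trajectory(ind, t, sc) == pytest.approx(
                control_trajectory(ind, t, sc)
            )

    @pytest.mark.parametrize("alpha", [0.25, 1.0])  # both branches vs delta=0.3
    def test_continuous_at_change_point(self, alpha):
        sc = noiseless(alpha=alpha)
        ind = individual(delta_i=1.0)
        eps = 1e-9
        left = treated_trajectory(ind, sc.delta - eps, sc)
        right = treated_trajectory(ind, sc.delta + eps, sc)
        assert left == pytest.approx(right, abs=1e-6)

    def test_late_branch_value_at_change_point(self):
        # with alpha >= delta both sides of the kink must equal
        # control + Delta + (gamma3 - gamma2)(delta - alpha)
        sc = noiseless(alpha=1.0, delta=0.3, gamma2=-2.0, gamma3=-1.9)
        ind = individual(delta_i=1.0)
        expected = (
            control_trajectory(ind, 0.3, sc)
            + 1.0
            + (sc.gamma3 - sc.gamma2) * (0.3 - 1.0)
        )
        assert treated_trajectory(ind, 0.3, sc) == pytest.approx(expected, abs=1e-9)

    def test_offset_kinks_only_at_delta_with_slope_gap(self):
        """The treated-minus-control offset is piecewise linear with a single
        slope change of (gamma3 - gamma2) at delta, on either branch."""
        for alpha in (0.25, 1.0):
            sc = noiseless(alpha=alpha, gamma2=0.0)
            ind = individual(delta_i=1.0)
            h = 1e-4
            for t0 in (0.1, 0.2, 0.8, 1.5):
                if abs(t0 - sc.delta) < 2 * h:
                    continue
                d = treatment_offset(ind, np.array([t0 - h, t0, t0 + h]), sc)
                curvature = d[0] - 2 * d[1] + d[2]
                assert curvature == pytest.approx(0.0, abs=1e-9)
            # after the change point the offset grows at exactly the slope
            # gap between the late treated and untreated segments
            slope_after = (
                treatment_offset(ind, sc.delta + 2 * h, sc)
                - treatment_offset(ind, sc.delta + h, sc)
            ) / h
            assert slope_after == pytest.approx(sc.gamma3 - sc.gamma2, abs=1e-6)


class TestSimulateTrials:
    def test_even_split_and_count(self):
        sc = ScenarioConfig(n1=1000, k=4, seed=0)
        trials = simulate_trials(sc, np.random.default_rng(0))
        assert len(trials) == 4
        assert all(t.n_treated + t.n_control == 250 for t in trials)

    def test_degenerate_variances_recover_are1_exactly(self):
        sc = ScenarioConfig(
            n1=200, k=2, sigma=0.0, nu_sq=1e-12, tau1_sq=0.5e-12,
            sigma0=1e-6, tau0_sq=0.5e-12, ARE1=1.0,
        )
        trials = simulate_trials(sc, np.random.default_rng(1))
        for t in trials:
            assert t.estimate == pytest.approx(1.0, abs=1e-5)

    def test_mean_estimate_converges_to_are1(self):
        sc = ScenarioConfig(n1=400, k=4, ARE1=1.5, pi=0.5)
        rng = np.random.default_rng(2)
        means = [
            np.mean([t.estimate for t in simulate_trials(sc, rng)])
            for _ in range(300)
        ]
        mc_se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(1.5, abs=4 * mc_se)

    def test_remainder_participants_assigned(self):
        sc = ScenarioConfig(n1=1001, k=4)
        trials = simulate_trials(sc, np.random.default_rng(3))
        sizes = sorted(t.n_treated + t.n_control for t in trials)
        assert sizes == [250, 250, 250, 251]


class TestSimulateCohort:
    def test_all_eligible_when_pi_near_one(self):
        sc = ScenarioConfig(n2=50, pi=1 - 1e-12)
        cohort = simulate_cohort(sc, np.random.default_rng(0))
        assert all(cohort.eligible.values())

    def test_noiseless_effect_equals_are1_via_extrapolation(self):
        """With all noise off, the observed eligible-stratum value at alpha
        minus the pre-offer-line extrapolation equals ARE1."""
        sc = ScenarioConfig(
            n2=20, sigma=0.0, nu_sq=1e-12, tau1_sq=0.5e-12, sigma0=1e-6,
            tau0_sq=0.5e-12, pi=1 - 1e-12, ARE1=1.0, ARE=1.0,
            obs_per_subject=(3, 3),
        )
        cohort = simulate_cohort(sc, np.random.default_rng(4))
        ind = SimulatedIndividual(id="x", Z=1, Delta=1.0, gamma0_i=sc.Gamma01)
        observed_at_alpha = treated_trajectory(ind, sc.alpha, sc)
        extrapolated = sc.Gamma01 + sc.gamma1 * sc.alpha  # pre-offer line
        assert observed_at_alpha - extrapolated == pytest.approx(1.0, abs=1e-6)
        assert cohort.n_subjects == 20

    def test_eligible_fraction_matches_pi(self):
        sc = ScenarioConfig(n2=4000, pi=0.7)
        cohort = simulate_cohort(sc, np.random.default_rng(5))
        frac = np.mean(list(cohort.eligible.values()))
        assert frac == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / 4000))

    def test_observation_times_within_window_and_counts_in_range(self):
        sc = ScenarioConfig(n2=200)
        cohort = simulate_cohort(sc, np.random.default_rng(6))
        assert cohort.records.time_years.between(-1, 3).all()
        counts = cohort.records.groupby("subject_id").size()
        assert counts.between(1, 8).all()

    def test_stratum_means_follow_mixture(self):
        """Mean effect is ARE1 among eligible, ARE2 among non-eligible and
        ARE overall (law of total expectation), via the realized scores at
        alpha versus the noise-free untreated extrapolation."""
        sc = ScenarioConfig(n2=6000, pi=0.5, ARE1=1.5, sigma=0.0, sigma0=1e-6,
                            tau0_sq=0.5e-12, obs_per_subject=(1, 1))
        rng = np.random.default_rng(7)
        z = []
        effects = []
        cohort = simulate_cohort(sc, rng)
        for sid, grp in cohort.records.groupby("subject_id"):
            t = grp.time_years.iloc[0]
            if t <= sc.delta or t > 3:  # use late segment for a clean read-out
                continue
            y = grp.adjusted_score.iloc[0]
            # invert the treated trajectory to the subject's Delta
            base = sc.Gamma01 + sc.gamma2 * t
            offset = y - base
            delta_i = (offset - (sc.gamma3 - sc.gamma2) * (t - sc.delta)) * (
                sc.alpha / sc.delta
            )
            effects.append(delta_i)
            z.append(cohort.eligible[sid])
        z = np.asarray(z)
        effects = np.asarray(effects)
        n1, n0 = z.sum(), (~z).sum()
        assert effects[z].mean() == pytest.approx(1.5, abs=3 * 1.0 / np.sqrt(n1))
        assert effects[~z].mean() == pytest.approx(
            sc.ARE2, abs=3 * 1.0 / np.sqrt(n0)
        )
        assert effects.mean() == pytest.approx(1.0, abs=3 * 1.1 / np.sqrt(len(z)))


class TestReproducibility:
    def test_identical_seed_identical_datasets(self):
        sc = ScenarioConfig(n1=120, k=3, n2=40)
        a = simulate_study(sc, seed=99)
        b = simulate_study(sc, seed=99)
        assert a.trials == b.trials
        pd.testing.assert_frame_equal(a.cohort.records, b.cohort.records)
        assert a.cohort.eligible == b.cohort.eligible

    def test_different_seed_differs(self):
        sc = ScenarioConfig(n1=120, k=3, n2=40)
        a = simulate_study(sc, seed=1)
        b = simulate_study(sc, seed=2)
        assert a.trials != b.trials


class TestScenarioValidation:
    def test_pi_bounds(self):
        with pytest.raises(ValueError):
            ScenarioConfig(pi=1.0)

    def test_tau_exceeding_total_variance_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(nu_sq=0.2, tau1_sq=0.25)

    def test_tiny_trials_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n1=10, k=4)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sc.yaml"
        path.write_text("n1: 500\nk: 5\nARE1: 1.5\npi: 0.5\n")
        sc = ScenarioConfig.from_yaml(path)
        assert (sc.n1, sc.k, sc.ARE1, sc.pi) == (500, 5, 1.5, 0.5)
        assert sc.zeta == pytest.approx(0.5)
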