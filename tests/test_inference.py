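"""Engine correctness: exact Bayes, free energy, policy arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avhsim.environment import env_step, initial_state
from avhsim.inference import (
    FactorizedPOMDP,
    LOG_FLOOR,
    bayesian_model_average,
    expected_free_energy,
    infer_states,
    policy_posterior,
    select_action,
)
from avhsim.model import LISTEN, SPEAK, build_policies, build_song_model


def single_factor_pomdp(A, D, horizon=1, n_actions=1):
    A = np.asarray(A, dtype=float)
    n = A.shape[1]
    B = np.repeat(np.eye(n)[:, :, None], n_actions, axis=2)
    return FactorizedPOMDP(
        A=[A],
        A_deps=[(0,)],
        B=[B],
        C=[np.full(A.shape[0], 1.0 / A.shape[0])],
        D=[np.asarray(D, dtype=float)],
        horizon=horizon,
    )


class TestExactBayes:
    def test_identity_likelihood_uniform_prior(self):
        """Observing outcome 0 through an identity mapping from a flat prior
        pins the state and yields F = ln 2."""
        pomdp = single_factor_pomdp(np.eye(2), [0.5, 0.5])
        res = infer_states(pomdp, [(0,)], [])
        np.testing.assert_allclose(res.qs[0][0], [1.0, 0.0], atol=1e-8)
        # the exp(-13) prior floor shifts F by ~4.5e-6 nats
        assert res.F == pytest.approx(math.log(2.0), abs=1e-5)

    def test_graded_likelihood_uniform_prior(self):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        pomdp = single_factor_pomdp(A, [0.5, 0.5])
        res = infer_states(pomdp, [(0,)], [])
        expected = A[0] / A[0].sum()  # posterior ∝ likelihood x flat prior
        np.testing.assert_allclose(res.qs[0][0], expected, atol=1e-8)

    def test_graded_prior_uses_floored_prior(self):
        """With a non-flat prior the posterior matches Bayes on the floored
        prior (structural priors are floored at exp(-13) by design)."""
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        D = np.array([0.6, 0.4])
        pomdp = single_factor_pomdp(A, D)
        res = infer_states(pomdp, [(0,)], [])
        post = A[0] * (D + LOG_FLOOR)
        np.testing.assert_allclose(res.qs[0][0], post / post.sum(), atol=1e-10)


class TestFreeEnergyDynamics:
    def observations_for(self, config_zeta, mode):
        model = build_song_model(zeta=config_zeta, transition_mode=mode)
        state = initial_state(6)
        obs = []
        for a in [LISTEN, LISTEN, SPEAK, LISTEN, SPEAK, LISTEN]:
            o, state = env_step(state, a)
            obs.append(o)
        return model, obs

    @pytest.mark.parametrize("zeta,mode", [(1.0, "veridical"), (3.0, "anomalous")])
    def test_free_energy_non_increasing_per_sweep(self, zeta, mode):
        model, obs = self.observations_for(zeta, mode)
        for policy in model.policies:
            res = infer_states(model, obs, policy)
            diffs = np.diff(res.F_trace)
            assert np.all(diffs <= 1e-9)

    def test_uninformative_likelihood_leaves_prior_predictive_chain(self):
        """At zeta = 0 audition carries no information, so the posterior is
        the prior chain: content follows the song from "It's" and the
        controlled factors follow the policy."""
        model, obs = self.observations_for(0.0, "veridical")
        policy = np.zeros(5, dtype=int)  # always listen
        res = infer_states(model, obs, policy)
        for t in range(6):
            assert np.argmax(res.qs[0][t]) == t  # word t of the song
            assert res.qs[0][t].max() > 0.99
            assert res.qs[1][t, 0] > 0.99  # listening throughout

    def test_future_timesteps_get_prior_predictive_beliefs(self):
        model, obs = self.observations_for(3.0, "veridical")
        res = infer_states(model, obs[:2], np.zeros(5, dtype=int))
        for t in range(2, 6):
            assert np.argmax(res.qs[0][t]) == t
            assert res.qs[1][t, 0] > 0.99

    def test_all_beliefs_normalized(self):
        model, obs = self.observations_for(1.0, "anomalous")
        res = infer_states(model, obs, model.policies[2])
        for q in res.qs:
            np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-8)


class TestExpectedFreeEnergy:
    def test_informative_channel_preferred(self):
        """Observing through an identity mapping resolves state uncertainty;
        a uniform mapping resolves nothing.  Verified against a brute-force
        enumeration of expected ambiguity and risk."""
        qs_uncertain = [np.full((2, 2), 0.5)]

        def oracle(A):
            # ambiguity: E_q(s) H[P(o|s)]; risk: KL(q(o) || C), C flat
            G = 0.0
            q = [0.5, 0.5]
            qo = [sum(A[o][s] * q[s] for s in range(2)) for o in range(2)]
            for s in range(2):
                H = -sum(A[o][s] * math.log(A[o][s]) for o in range(2) if A[o][s] > 0)
                G += q[s] * H
            G += sum(qo[o] * (math.log(qo[o]) - math.log(0.5)) for o in range(2))
            return G

        A_inf = np.eye(2)
        A_unif = np.full((2, 2), 0.5)
        g_inf = expected_free_energy(single_factor_pomdp(A_inf, [0.5, 0.5], horizon=2), qs_uncertain, [0], 1)
        g_unif = expected_free_energy(single_factor_pomdp(A_unif, [0.5, 0.5], horizon=2), qs_uncertain, [0], 1)
        assert g_inf == pytest.approx(oracle(A_inf), abs=1e-4)
        assert g_unif == pytest.approx(oracle(A_unif), abs=1e-4)
        assert g_inf < g_unif

    def test_identical_predictions_give_identical_G(self):
        """Two policies with identical predicted state-outcome
        distributions have identical expected free energies."""
        pomdp = single_factor_pomdp(np.eye(2), [0.5, 0.5], horizon=3, n_actions=2)
        qs = [np.full((3, 2), 0.5)]
        g_a = expected_free_energy(pomdp, qs, np.array([[0], [0]]), 1)
        g_b = expected_free_energy(pomdp, qs, np.array([[1], [1]]), 1)
        assert g_a == g_b

    def test_song_policies_nearly_epistemically_equivalent(self, suite):
        """Listening and speaking policies predict near-identical outcome
        information (a word or silence through equally sharp columns), so
        G barely separates them -- policy selection is evidence-driven."""
        for trial in suite[0].values():
            for snap in trial.beliefs:
                G = snap.G_per_policy
                assert G.max() - G.min() < 1e-2

    def test_deterministic_likelihood_has_zero_ambiguity(self):
        delta_qs = [np.tile([1.0, 0.0], (2, 1))]
        pomdp = single_factor_pomdp(np.eye(2), [0.5, 0.5], horizon=2)
        g = expected_free_energy(pomdp, delta_qs, [0], 1)
        # ambiguity 0; risk = KL(one-hot || flat) = ln 2
        assert g == pytest.approx(math.log(2.0), abs=1e-4)


class TestPolicyPosterior:
    def test_flat_when_everything_ties(self):
        np.testing.assert_allclose(policy_posterior([0, 0, 0], [2.0, 2.0, 2.0], 16.0), 1 / 3)

    def test_zero_gamma_ignores_G(self):
        np.testing.assert_allclose(policy_posterior([0, 0, 0], [0.0, 5.0, -3.0], 0.0), 1 / 3)

    def test_evidence_update_by_hand(self):
        out = policy_posterior([0.0, math.log(2), math.log(2)], [0.0, 0.0, 0.0], 16.0)
        np.testing.assert_allclose(out, [0.5, 0.25, 0.25], atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        F=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        G=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        shift=st.floats(-10, 10),
    )
    def test_shift_invariance(self, F, G, shift):
        base = policy_posterior(F, G, 4.0)
        np.testing.assert_allclose(policy_posterior(np.add(F, shift), G, 4.0), base, atol=1e-10)
        np.testing.assert_allclose(policy_posterior(F, np.add(G, shift), 4.0), base, atol=1e-10)


class TestBayesianModelAverage:
    def setup_method(self):
        self.qs = [
            [np.array([[1.0, 0.0, 0.0]])],
            [np.array([[0.0, 1.0, 0.0]])],
            [np.array([[0.0, 0.0, 1.0]])],
        ]

    def test_one_hot_policy_selects_its_beliefs(self):
        out = bayesian_model_average(self.qs, [0.0, 1.0, 0.0])
        np.testing.assert_allclose(out[0], [[0.0, 1.0, 0.0]])

    def test_weighted_mixture(self):
        out = bayesian_model_average(self.qs, [0.2, 0.3, 0.5])
        np.testing.assert_allclose(out[0], [[0.2, 0.3, 0.5]], atol=1e-12)


class TestSelectAction:
    def test_marginal_over_prescribing_policies(self):
        policies = np.array([[LISTEN], [SPEAK], [LISTEN]])
        assert select_action([0.45, 0.10, 0.45], policies, 0) == LISTEN

    def test_exact_tie_breaks_toward_listening(self):
        policies = np.array([[LISTEN], [SPEAK], [SPEAK]])
        assert select_action([0.5, 0.25, 0.25], policies, 0) == LISTEN

    def test_sampling_is_reproducible(self):
        policies = build_policies(6)
        q = [0.55, 0.15, 0.30]
        draws1 = [
            select_action(q, policies, 1, mode="sample", rng=np.random.default_rng(7))
            for _ in range(5)
        ]
        draws2 = [
            select_action(q, policies, 1, mode="sample", rng=np.random.default_rng(7))
            for _ in range(5)
        ]
        assert draws1 == draws2

    def test_sample_mode_requires_generator(self):
        with pytest.raises(ValueError):
            select_action([1.0, 0.0, 0.0], build_policies(6), 0, mode="sample")


class TestHighPrecisionSanity:
    def test_no_hallucination_possible_at_high_precision(self):
        """With zeta >= 3 and the veridical narrative, every one of the 32
        forced action sequences leaves the belief-averaged listening
        probability below one half at every silent timestep."""
        from itertools import product

        from avhsim.experiments import TrialConfig, run_trial

        cfg = TrialConfig(zeta=3.0, transition_mode="veridical")
        for seq in product([LISTEN, SPEAK], repeat=5):
            trial = run_trial(cfg, forced_actions=list(seq))
            marg = trial.final_beliefs.q_marginal
            for t, obs in enumerate(trial.observations):
                if not obs.sound_present:
                    assert marg[1][t, 0] < 0.5, (seq, t + 1)

    def test_marginal_bookkeeping_consistent(self, suite):
        """Recomputing the Bayesian model average from the stored
        policy-conditioned beliefs reproduces the stored marginals."""
        for trial in suite[0].values():
            for snap in trial.beliefs:
                recomputed = snap.recomputed_marginal()
                for f in range(3):
                    np.testing.assert_array_equal(recomputed[f], snap.q_marginal[f])
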