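"""Inference: filtering/smoothing vs enumeration, decoding, correction, sampling."""

import numpy as np
import pytest

from conftest import (
    cycle_model,
    oracle_filtered,
    oracle_gammas,
    oracle_viterbi_logprob,
    random_sequence,
    random_tiny_model,
)
from cscg import infer
from cscg.infer import NoPathError, SoftEvidence
from cscg.model import ActionObservationSequence, CloneAllocation, create_model


class TestFilter:
    def test_hard_equals_one_hot_soft(self, rng):
        model = random_tiny_model(rng)
        seq = random_sequence(model, rng)
        hard = infer.filter(model, seq)
        soft = infer.filter(model, SoftEvidence.from_hard(seq, model.n_obs))
        assert np.allclose(hard.activations, soft.activations, atol=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            model = random_tiny_model(rng)
            seq = random_sequence(model, rng)
            trace = infer.filter(model, seq)
            assert np.max(np.abs(trace.activations - oracle_filtered(model, seq))) < 1e-10

    def test_rows_are_distributions(self, rng):
        model = random_tiny_model(rng)
        seq = random_sequence(model, rng)
        trace = infer.filter(model, seq)
        assert np.allclose(trace.activations.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_evidence_is_pure_prediction(self, rng):
        """A totally uninformative step leaves the one-step prediction."""
        model = random_tiny_model(rng)
        E = model.n_obs
        like = np.zeros((3, E))
        like[0, int(rng.integers(E))] = 1.0
        like[1] = 1.0  # uniform: evidence cancels
        like[2, int(rng.integers(E))] = 1.0
        a = rng.integers(0, model.n_actions, 2)
        trace = infer.filter(model, SoftEvidence(like, a))
        predicted = trace.activations[0] @ model.transitions[:, a[0], :]
        assert np.allclose(trace.activations[1], predicted / predicted.sum(), atol=1e-12)

    def test_all_zero_evidence_row_rejected(self, rng):
        model = random_tiny_model(rng)
        like = np.ones((2, model.n_obs))
        like[1] = 0.0
        with pytest.raises(ValueError):
            SoftEvidence(like)


class TestSmooth:
    def test_last_step_equals_filtered(self, rng):
        model = random_tiny_model(rng)
        seq = random_sequence(model, rng)
        filt = infer.filter(model, seq)
        smth = infer.smooth(model, seq)
        assert np.allclose(smth.activations[-1], filt.activations[-1], atol=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            model = random_tiny_model(rng)
            seq = random_sequence(model, rng)
            trace = infer.smooth(model, seq)
            assert np.max(np.abs(trace.activations - oracle_gammas(model, seq))) < 1e-10


class TestViterbi:
    def test_unique_path_on_deterministic_cycle(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1, 2, 0], np.zeros(3, dtype=np.int64))
        path = infer.viterbi_decode(tiny_cycle, seq)
        assert np.array_equal(path.states, [0, 1, 2, 0])
        assert path.logprob == pytest.approx(0.0, abs=1e-12)

    def test_logprob_matches_enumeration_argmax(self, rng):
        for _ in range(25):
            model = random_tiny_model(rng)
            seq = random_sequence(model, rng)
            path = infer.viterbi_decode(model, seq)
            assert path.logprob == pytest.approx(
                oracle_viterbi_logprob(model, seq), abs=1e-10
            )

    def test_no_path_raises(self, tiny_cycle):
        with pytest.raises(NoPathError):
            infer.viterbi_decode(
                tiny_cycle, ActionObservationSequence([0, 2], np.zeros(1, dtype=np.int64))
            )

    def test_ties_break_to_lowest_state(self):
        model = create_model(CloneAllocation([2, 1]), 1, init="uniform")
        seq = ActionObservationSequence([0, 1], np.zeros(1, dtype=np.int64))
        assert infer.viterbi_decode(model, seq).states[0] == 0


class TestErrorCorrection:
    def test_impossible_symbol_replaced(self, tiny_cycle):
        soft = tiny_cycle.smoothed(1e-6)
        soft.prior = np.full(3, 1 / 3)
        clean = [0, 1, 2, 0, 1, 2, 0]
        noisy = [0, 1, 2, 1, 1, 2, 0]  # the 4th symbol breaks the cycle
        seq = ActionObservationSequence(noisy, np.zeros(6, dtype=np.int64))
        fixed, post = infer.correct_errors(soft, seq, noise_rate=0.2)
        assert np.array_equal(fixed.observations, clean)
        assert post.shape == (7, 3)

    def test_consistent_sequence_untouched(self, tiny_cycle):
        soft = tiny_cycle.smoothed(1e-6)
        seq = ActionObservationSequence([0, 1, 2, 0, 1], np.zeros(4, dtype=np.int64))
        fixed, _ = infer.correct_errors(soft, seq, noise_rate=0.2)
        assert np.array_equal(fixed.observations, seq.observations)

    def test_invalid_noise_rate(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1], np.zeros(1, dtype=np.int64))
        with pytest.raises(ValueError):
            infer.correct_errors(tiny_cycle, seq, noise_rate=1.0)


class TestSampling:
    def test_deterministic_cycle_repeats(self, tiny_cycle):
        seq, states = infer.sample(tiny_cycle, 9, seed=0)
        assert np.array_equal(seq.observations, [0, 1, 2] * 3)
        assert np.array_equal(states, [0, 1, 2] * 3)

    def test_empirical_frequencies_match_transitions(self, rng):
        from scipy import stats

        model = random_tiny_model(rng)
        n = 100_000
        seq, states = infer.sample(model, n, seed=1)
        a = seq.actions
        H = model.n_states
        counts = np.zeros((H, model.n_actions, H))
        np.add.at(counts, (states[:-1], a, states[1:]), 1.0)
        visits = counts.reshape(H, -1).sum(axis=1)
        for i in np.flatnonzero(visits > 500):
            obs = counts[i].ravel()
            p = model.transitions[i].ravel()
            keep = p > 1e-4
            pval = stats.chisquare(
                obs[keep], visits[i] * p[keep] / p[keep].sum()
            ).pvalue
            assert pval > 1e-4  # generous: guards correctness, not luck

    def test_invalid_start_rejected(self, tiny_cycle):
        with pytest.raises(ValueError):
            infer.sample(tiny_cycle, 5, start=17)

    def test_replay_forced_next_symbol(self, tiny_cycle):
        prefix = ActionObservationSequence([0, 1], np.zeros(1, dtype=np.int64))
        draws = {infer.replay_observation_sample(tiny_cycle, prefix, seed=s)
                 for s in range(5)}
        assert draws == {2}

    def test_replay_distribution_matches_forward_prediction(self, rng):
        model = random_tiny_model(rng)
        prefix = random_sequence(model, rng, max_len=4)
        trace = infer.filter(model, prefix)
        nxt = trace.activations[-1] @ model.action_marginal()
        dist = np.add.reduceat(nxt, model.allocation.offsets[:-1])
        dist /= dist.sum()
        n = 2000
        draws = np.array([
            infer.replay_observation_sample(model, prefix, seed=s) for s in range(n)
        ])
        emp = np.bincount(draws, minlength=model.n_obs) / n
        se = np.sqrt(dist * (1 - dist) / n)
        assert np.all(np.abs(emp - dist) <= 3 * se + 5e-3)


class TestEnvironmentPosterior:
    def test_single_environment_is_certain(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1, 2], np.zeros(2, dtype=np.int64))
        post = infer.environment_posterior(tiny_cycle, [np.arange(3)], seq)
        assert np.allclose(post, 1.0)

    def test_identical_environments_stay_at_prior_ratio(self):
        """Two identical halves of a model share the posterior evenly."""
        alloc = CloneAllocation.uniform(2, 2)  # two clones per symbol
        H = alloc.n_states
        T = np.zeros((H, 1, H))
        # two parallel deterministic cycles over clones (0,2) and (1,3)
        T[0, 0, 2] = T[2, 0, 0] = 1.0
        T[1, 0, 3] = T[3, 0, 1] = 1.0
        from cscg.model import CSCGModel

        model = CSCGModel(alloc, 1, np.full(H, 0.25), T)
        seq = ActionObservationSequence([0, 1, 0, 1], np.zeros(3, dtype=np.int64))
        post = infer.environment_posterior(model, [np.array([0, 2]), np.array([1, 3])], seq)
        assert np.allclose(post, 0.5, atol=1e-12)

    def test_overlapping_sets_rejected(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1], np.zeros(1, dtype=np.int64))
        with pytest.raises(ValueError):
            infer.environment_posterior(
                tiny_cycle, [np.array([0, 1]), np.array([1, 2])], seq
            )

    def test_next_symbol_prediction_on_cycle(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1, 2, 0], np.zeros(3, dtype=np.int64))
        preds = infer.predict_next_observation(tiny_cycle, seq)
        assert np.allclose(preds[0], [0, 1, 0])
        assert infer.next_symbol_accuracy(tiny_cycle, seq, burn_in=0) == 1.0
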