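"""Learning: message passing vs enumeration, EM properties, refinement, online EM."""

import numpy as np
import pytest

from conftest import (
    cycle_model,
    oracle_gammas,
    oracle_loglik,
    oracle_xi_counts,
    random_sequence,
    random_tiny_model,
)
from cscg import learn
from cscg.learn import EMConfig, SufficientStats, forward_backward, m_step
from cscg.model import ActionObservationSequence, CloneAllocation, create_model


class TestForwardBackwardOracle:
    def test_matches_enumeration_on_random_models(self):
        """Loglik, gamma and xi agree with brute-force path enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            model = random_tiny_model(rng)
            seq = random_sequence(model, rng)
            trace = forward_backward(model, seq)
            assert trace.loglik == pytest.approx(oracle_loglik(model, seq), abs=1e-10)
            g_oracle = oracle_gammas(model, seq)
            off = model.allocation.offsets
            for n in range(len(seq)):
                g = np.zeros(model.n_states)
                x = seq.observations[n]
                g[off[x]:off[x + 1]] = trace.gamma(n)
                assert np.max(np.abs(g - g_oracle[n])) < 1e-10
            stats = learn.e_step(model, seq)
            assert np.max(np.abs(stats.counts - oracle_xi_counts(model, seq))) < 1e-10

    def test_deterministic_cycle_has_probability_one(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1, 2, 0, 1], np.zeros(4, dtype=np.int64))
        assert forward_backward(tiny_cycle, seq).loglik == pytest.approx(0.0, abs=1e-12)

    def test_single_observation_loglik_is_prior_mass(self):
        model = create_model(CloneAllocation([3, 2]), 1, seed=1)
        seq = ActionObservationSequence([1])
        expected = np.log(model.prior[3:5].sum())
        assert forward_backward(model, seq).loglik == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_sequence_flagged_not_raised(self, tiny_cycle):
        seq = ActionObservationSequence([0, 2], np.zeros(1, dtype=np.int64))
        assert forward_backward(tiny_cycle, seq).loglik == -np.inf

    def test_deterministic_cycle_one_hot_xi(self, tiny_cycle):
        seq = ActionObservationSequence([0, 1, 2, 0], np.zeros(3, dtype=np.int64))
        stats = learn.e_step(tiny_cycle, seq)
        assert np.all(np.isin(stats.counts, [0.0, 1.0, 2.0]))
        assert stats.counts.sum() == len(seq) - 1


class TestMStep:
    def _stats(self, counts, prior_counts=None):
        counts = np.asarray(counts, dtype=float)
        H = counts.shape[0]
        alloc = CloneAllocation([H])  # one symbol, H clones: shapes only
        pc = np.ones(H) if prior_counts is None else np.asarray(prior_counts, float)
        return SufficientStats(counts[:, None, :], pc, alloc, 1)

    def test_pseudocount_formula(self):
        model = m_step(self._stats([[2.0, 0.0], [1.0, 1.0]]), pseudocount=1.0)
        assert np.allclose(model.transitions[0, 0], [0.75, 0.25])

    def test_zero_counts_with_pseudocount_gives_uniform(self):
        model = m_step(self._stats(np.zeros((3, 3))), pseudocount=0.5)
        assert np.allclose(model.transitions, 1.0 / 3.0)

    def test_zero_counts_without_pseudocount_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            m_step(self._stats([[0.0, 0.0], [1.0, 0.0]]), pseudocount=0.0)

    def test_large_pseudocount_approaches_uniform_monotonically(self):
        stats = self._stats([[5.0, 1.0], [2.0, 2.0]])
        tv_prev = np.inf
        for kappa in (0.1, 1.0, 10.0, 100.0):
            T = m_step(self._stats([[5.0, 1.0], [2.0, 2.0]]), kappa).transitions
            tv = np.abs(T - 0.5).sum()
            assert tv < tv_prev
            tv_prev = tv


class TestEMFit:
    @pytest.mark.parametrize("normalization", ["conditional", "joint"])
    def test_penalized_loglik_monotone(self, normalization, rng):
        model = random_tiny_model(rng)
        seqs = [random_sequence(model, rng, max_len=30) for _ in range(2)]
        cfg = EMConfig(
            max_iters=40, pseudocount=1e-2, tol=0.0, seed=0,
            normalization=normalization,
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            _, trace = learn.em_fit(model, seqs, cfg)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9)

    def test_fitted_model_satisfies_joint_invariants(self, rng):
        model = random_tiny_model(rng)
        seq = random_sequence(model, rng, max_len=40)
        fitted, _ = learn.em_fit(model, [seq], EMConfig(max_iters=10, pseudocount=1e-3))
        fitted.validate()

    def test_action_free_stream_equals_single_action_cscg(self, rng):
        """A cloned HMM is exactly a CSCG with one action."""
        model = create_model(CloneAllocation.uniform(3, 2), 1, seed=4)
        x = rng.integers(0, 3, 50)
        bare = ActionObservationSequence(x.copy())
        explicit = ActionObservationSequence(x.copy(), np.zeros(49, dtype=np.int64))
        cfg = EMConfig(max_iters=15, pseudocount=1e-3, seed=4)
        _, t1 = learn.em_fit(model, [bare], cfg)
        _, t2 = learn.em_fit(model, [explicit], cfg)
        assert t1 == t2

    def test_multiple_sequences_are_additive(self, rng):
        model = random_tiny_model(rng)
        s1 = random_sequence(model, rng)
        s2 = random_sequence(model, rng)
        joint = learn.e_step(model, s1).add(learn.e_step(model, s2))
        separate = learn.e_step(model, s1).counts + learn.e_step(model, s2).counts
        assert np.allclose(joint.counts, separate)

    def test_parameter_recovery_small_cscg(self):
        """Transitions of a known small CSCG are recovered within TV 0.05."""
        from conftest import identifiable_small_cscg, recovery_tv
        from cscg import infer

        true = identifiable_small_cscg()
        seq, _ = infer.sample(true, 50_000, seed=3)
        fit0 = create_model(true.allocation, 2, seed=1)
        fitted, _ = learn.em_fit(
            fit0, [seq], EMConfig(max_iters=200, pseudocount=1e-4, tol=1e-12,
                                  n_restarts=3, seed=1)
        )
        assert recovery_tv(true, fitted) <= 0.05

    def test_block_cost_independent_of_alphabet_size(self):
        """Forward cost counts clone-block products, not alphabet size."""
        small = create_model(CloneAllocation.uniform(2, 4), 1, seed=0)
        large = create_model(CloneAllocation.uniform(50, 4), 1, seed=0)
        seq_small = ActionObservationSequence([0, 1] * 10, np.zeros(19, dtype=np.int64))
        seq_large = ActionObservationSequence([7, 31] * 10, np.zeros(19, dtype=np.int64))
        assert learn.forward_op_count(small, seq_small) == learn.forward_op_count(
            large, seq_large
        )


class TestViterbiTraining:
    def test_hard_fixed_point_is_unchanged(self):
        model = cycle_model(3)
        seq = ActionObservationSequence([0, 1, 2] * 5, np.zeros(14, dtype=np.int64))
        refined = learn.viterbi_train(model, [seq], EMConfig(max_iters=5))
        assert np.array_equal(refined.transitions, model.transitions)

    def test_redundant_clones_pruned_on_cycle_data(self):
        alloc = CloneAllocation.uniform(3, 2)
        model = create_model(alloc, 1, seed=0)
        seq = ActionObservationSequence([0, 1, 2] * 20, np.zeros(59, dtype=np.int64))
        fitted, _ = learn.em_fit(model, [seq], EMConfig(max_iters=50, pseudocount=1e-3))
        refined = learn.viterbi_train(fitted, [seq], EMConfig(max_iters=20))
        # steady state: one clone per symbol (the first step may pass through
        # a transient start clone before joining the cycle)
        from cscg.infer import viterbi_decode

        steady = np.unique(viterbi_decode(refined, seq).states[1:])
        assert steady.size == 3
        symbols = alloc.symbol_of_state()[steady]
        assert sorted(symbols.tolist()) == [0, 1, 2]

    def test_prune_keeps_decoded_path_likelihood(self):
        from cscg import infer

        alloc = CloneAllocation.uniform(3, 2)
        model = create_model(alloc, 1, seed=0)
        seq = ActionObservationSequence([0, 1, 2] * 20, np.zeros(59, dtype=np.int64))
        fitted, _ = learn.em_fit(model, [seq], EMConfig(max_iters=50, pseudocount=1e-3))
        refined = learn.viterbi_train(fitted, [seq], EMConfig(max_iters=20))
        before = infer.viterbi_decode(refined, seq).logprob
        pruned, old_ids = learn.prune_model(refined, learn.used_states(refined, [seq]))
        after = infer.viterbi_decode(pruned, seq).logprob
        assert after == pytest.approx(before, abs=1e-9)
        assert pruned.n_states == old_ids.size


class TestMemorize:
    def test_memorized_chain_reproduces_sequence(self):
        """A unique sequence is memorized as a deterministic clone chain."""
        seq = ActionObservationSequence(
            [3, 0, 1, 0, 1, 2], np.zeros(5, dtype=np.int64)
        )
        model = learn.memorize(CloneAllocation.uniform(4, 4), 1, [seq])
        assert learn.loglikelihood(model, seq) > -0.01
        from cscg import infer

        path = infer.viterbi_decode(model, seq).states
        assert np.unique(path).size == len(seq)  # fresh clone per repeat context

    def test_shared_context_reuses_clones(self):
        s1 = ActionObservationSequence([0, 1, 2], np.zeros(2, dtype=np.int64))
        model = learn.memorize(CloneAllocation.uniform(3, 3), 1, [s1, s1])
        from cscg import infer

        p = infer.viterbi_decode(model, s1).states
        assert np.unique(p).size == 3  # identical episodes share one chain


class TestSplitRefine:
    def test_splits_artificially_merged_room_cells(self):
        """A clone covering two cells is split apart by context conflicts."""
        from conftest import perfect_room_model
        from cscg import envs, infer
        from cscg.model import CSCGModel

        room = envs.make_room(4, 4, 8, seed=5)
        model, state_of = perfect_room_model(room)
        # enlarge the allocation so free clones exist, then merge two cells
        # of the same symbol by rerouting all inbound transitions
        alloc = CloneAllocation(model.allocation.clones_per_obs + 1)
        H = alloc.n_states
        old_off = model.allocation.offsets
        new_off = alloc.offsets
        remap = np.concatenate([
            np.arange(old_off[j], old_off[j + 1]) + (new_off[j] - old_off[j])
            for j in range(model.n_obs)
        ])
        T = np.zeros((H, 4, H))
        T[np.ix_(remap, np.arange(4), remap)] = model.transitions
        prior = np.zeros(H)
        prior[remap] = model.prior
        symbol_of = alloc.symbol_of_state()
        # pick a symbol with two cells and merge their clones
        from collections import Counter

        per_symbol = Counter(symbol_of[remap[list(state_of.values())]].tolist())
        sym = next(s for s, c in per_symbol.items() if c >= 2)
        zs = [remap[z] for c, z in state_of.items() if room.observation(c) == sym]
        keep, drop = int(zs[0]), int(zs[1])
        T[:, :, keep] += T[:, :, drop]
        T[:, :, drop] = 0.0
        T[keep] = (T[keep] + T[drop]) / 2.0
        T[drop] = 0.0
        rs = T.reshape(H, -1).sum(axis=1)
        T[rs <= 0] = 1.0 / (4 * H)
        T /= T.reshape(H, -1).sum(axis=1)[:, None, None]
        prior[keep] += prior[drop]
        prior[drop] = 0.0
        prior /= prior.sum()
        merged = CSCGModel(alloc, 4, prior, T)
        walk, _ = envs.random_walk(room, 8000, seed=5)
        cfg = EMConfig(max_iters=200, pseudocount=1e-3, tol=1e-11, seed=5)
        before = learn.used_states(merged, [walk]).size
        fixed = learn.split_merge_refine(merged, [walk], cfg)
        after = learn.used_states(fixed, [walk]).size
        assert after > before  # the merged cell pair was separated
        assert after == 16     # one clone per cell
        from cscg.infer import next_symbol_accuracy

        test, _ = envs.random_walk(room, 500, seed=55)
        assert next_symbol_accuracy(fixed.smoothed(1e-9), test) == 1.0

    def test_no_change_on_perfect_model(self):
        from conftest import perfect_room_model
        from cscg import envs

        room = envs.make_room(4, 4, 8, seed=5)
        model, _ = perfect_room_model(room)
        walk, _ = envs.random_walk(room, 4000, seed=5)
        cfg = EMConfig(max_iters=50, pseudocount=1e-3, seed=5)
        refined = learn.split_merge_refine(model, [walk], cfg, cycles=2)
        assert learn.used_states(refined, [walk]).size == 16


class TestEmissionLearning:
    def test_transitions_bitwise_frozen(self, rng):
        model = cycle_model(3)
        model.prior = np.full(3, 1 / 3)
        model.emission = np.full((3, 3), 1 / 3)
        seq = ActionObservationSequence([0, 1, 2] * 10, np.zeros(29, dtype=np.int64))
        out, _ = learn.learn_emission(model, [seq], EMConfig(max_iters=20, pseudocount=1e-9))
        assert np.array_equal(out.transitions, model.transitions)

    def test_single_symbol_world_converges_to_one_hot(self):
        model = cycle_model(3)
        model.prior = np.full(3, 1 / 3)
        model.emission = np.full((3, 2), 0.5)
        # relabel: cycle states now all emit symbol 1 in the new world
        seq = ActionObservationSequence(np.ones(30, dtype=np.int64),
                                        np.zeros(29, dtype=np.int64))
        out, _ = learn.learn_emission(model, [seq], EMConfig(max_iters=50, pseudocount=0.0))
        assert np.allclose(out.emission[:, 1], 1.0, atol=1e-6)


class TestOnlineEM:
    def test_first_batch_equals_batch_m_step(self, rng):
        model = random_tiny_model(rng)
        batch = random_sequence(model, rng, max_len=30)
        state = learn.OnlineEMState.initial(model, memory=0.5)
        _, updated = learn.online_em_update(state, model, batch)
        stats = learn.e_step(model, batch)
        expected = m_step(stats, 0.0, fallback=model)
        assert np.allclose(updated.transitions, expected.transitions, atol=1e-12)

    def test_small_memory_tracks_last_batch(self, rng):
        model = random_tiny_model(rng)
        b1 = random_sequence(model, rng, max_len=20)
        b2 = random_sequence(model, rng, max_len=20)
        state = learn.OnlineEMState.initial(model, memory=1e-9)
        state, m1 = learn.online_em_update(state, model, b1)
        state, m2 = learn.online_em_update(state, m1, b2)
        only_b2 = learn.e_step(m1, b2)
        expected = m_step(only_b2, 0.0, fallback=m1)
        assert np.allclose(m2.transitions, expected.transitions, atol=1e-6)

    def test_memory_outside_unit_interval_rejected(self, rng):
        model = random_tiny_model(rng)
        with pytest.raises(ValueError):
            learn.OnlineEMState.initial(model, memory=1.0)

    def test_room_switch_shifts_transition_mass(self):
        """After the stream moves to room B, mass on B-only bigrams rises."""
        from cscg import envs

        room_a = envs.make_room(3, 3, 4, seed=0)
        room_b = envs.make_room(3, 3, 4, seed=9)
        alloc = CloneAllocation.uniform(4, 3)
        model = create_model(alloc, 4, seed=0)
        state = learn.OnlineEMState.initial(model, memory=0.4)
        symbol_of = alloc.symbol_of_state()

        def b_only_mass(m):
            # bigram mass on symbol pairs adjacent in room B but not in room A
            def bigrams(room):
                out = set()
                for cell in map(tuple, room.free_cells()):
                    for k in room.legal_actions(cell):
                        nxt = room.step(cell, int(k))
                        out.add((room.observation(cell), room.observation(nxt)))
                return out

            target = bigrams(room_b) - bigrams(room_a)
            total = 0.0
            W = m.action_marginal()
            for i in range(m.n_states):
                for j in range(m.n_states):
                    if (symbol_of[i], symbol_of[j]) in target:
                        total += W[i, j]
            return total

        masses = []
        for b in range(6):
            room = room_a if b < 2 else room_b
            batch, _ = envs.random_walk(room, 300, seed=b)
            state, model = learn.online_em_update(state, model, batch)
            masses.append(b_only_mass(model))
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(masses[2:], masses[3:]))
        assert masses[-1] > masses[1]
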