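"""Environment generators and walkers: geometry, aliasing, reproducibility."""

import numpy as np
import pytest

from cscg import envs
from cscg.envs import WALL, GridEnvironment


class TestMakeRoom:
    def test_shape_and_alphabet(self):
        room = envs.make_room(6, 8, 4, seed=1)
        assert room.shape == (6, 8)
        assert set(np.unique(room.grid)) <= set(range(4))
        assert np.unique(room.grid).size == 4  # every symbol used

    def test_uniform_interior(self):
        room = envs.make_room(6, 8, 5, seed=1, uniform_interior=True)
        assert np.all(room.grid[1:-1, 1:-1] == room.grid[1, 1])

    def test_seed_determinism(self):
        a = envs.make_room(5, 5, 3, seed=9)
        b = envs.make_room(5, 5, 3, seed=9)
        assert np.array_equal(a.grid, b.grid)

    def test_too_many_symbols_rejected(self):
        with pytest.raises(ValueError):
            envs.make_room(2, 2, 5)

    def test_json_round_trip(self, tmp_path):
        room = envs.make_room(4, 4, 3, seed=2)
        room.to_json(tmp_path / "room.json")
        back = GridEnvironment.from_json(tmp_path / "room.json")
        assert np.array_equal(back.grid, room.grid)
        assert back.n_obs == room.n_obs


class TestOverlappingRooms:
    def test_patches(self):
        room1, room2, ann = envs.make_overlapping_rooms(seed=3)
        P = ann["patch_size"]
        assert room1.shape == (8, 6) and room2.shape == (8, 6)
        (r1, c1), (r2, c2) = ann["overlap_room1"], ann["overlap_room2"]
        patch1 = room1.grid[r1:r1 + P, c1:c1 + P]
        patch2 = room2.grid[r2:r2 + P, c2:c2 + P]
        assert np.array_equal(patch1, patch2)
        (cr, cc) = ann["confounder_room1"]
        conf = room1.grid[cr:cr + P, cc:cc + P]
        assert np.array_equal(conf, patch1)
        # confounder and overlap occupy disjoint cells of room 1
        assert {(cr + i, cc + j) for i in range(P) for j in range(P)}.isdisjoint(
            {(r1 + i, c1 + j) for i in range(P) for j in range(P)}
        )

    def test_patch_copy_counts(self):
        """Exactly two copies of the shared patch in room 1, one in room 2."""
        room1, room2, ann = envs.make_overlapping_rooms(seed=3)
        P = ann["patch_size"]
        (r1, c1) = ann["overlap_room1"]
        patch = room1.grid[r1:r1 + P, c1:c1 + P]

        def count(grid):
            h, w = grid.shape
            return sum(
                np.array_equal(grid[r:r + P, c:c + P], patch)
                for r in range(h - P + 1) for c in range(w - P + 1)
            )

        assert count(room1.grid) == 2
        assert count(room2.grid) == 1


class TestHierarchicalMaze:
    def test_structure(self):
        maze, room_labels, hyper_labels = envs.make_hierarchical_maze(seed=4)
        free = maze.grid[maze.grid != WALL]
        assert set(np.unique(free)) <= set(range(13))
        assert np.unique(room_labels[room_labels >= 0]).size == 16
        # bridges carry the dedicated symbol
        assert np.all(maze.grid[room_labels == -2] == 12)

    def test_removing_bridges_gives_16_components(self):
        import networkx as nx

        maze, room_labels, _ = envs.make_hierarchical_maze(seed=4)
        g = nx.Graph()
        for r, c in np.argwhere((maze.grid != WALL) & (room_labels != -2)):
            g.add_node((r, c))
            for dr, dc in ((0, 1), (1, 0)):
                nr, nc = r + dr, c + dc
                if maze.is_free(nr, nc) and room_labels[nr, nc] != -2:
                    g.add_edge((r, c), (nr, nc))
        assert nx.number_connected_components(g) == 16


class TestModularGraph:
    def test_degrees_and_communities(self):
        graph, communities = envs.make_modular_graph(seed=0)
        assert graph.n_nodes == 15
        degrees = [len(s) for s in graph.successors]
        assert degrees == [4] * 15
        assert np.array_equal(communities, np.repeat([0, 1, 2], 5))

    def test_observations_aliased_across_clusters(self):
        graph, _ = envs.make_modular_graph(seed=0)
        assert np.unique(graph.observations).size < 15
        for c in range(3):
            assert sorted(graph.observations[c * 5:(c + 1) * 5]) == list(range(5))


class TestLapTrack:
    def test_default_sequence(self):
        seq, ann = envs.make_lap_track()
        assert len(seq) == 50
        assert seq.observations[0] == ann["start_symbol"]
        assert seq.observations[-1] == ann["reward_symbol"]
        corridor = seq.observations[1:-1]
        assert np.array_equal(corridor, np.tile(np.arange(12), 4))

    def test_elongation_repeats_corridor_only(self):
        seq, _ = envs.make_lap_track()
        elong, _ = envs.make_lap_track(elongation=1)
        assert len(elong) == 2 + 96
        # deduplicating consecutive repeats recovers the original corridor
        obs = elong.observations
        dedup = obs[np.concatenate(([True], obs[1:] != obs[:-1]))]
        # consecutive duplicates only occur within the corridor here
        assert np.array_equal(dedup, seq.observations)


class TestRouteEnvironments:
    def test_tmaze_shared_stem(self):
        rg = envs.make_route_environment("tmaze_fig8", seed=0)
        left = [rg.observations[i] for i in rg.annotations["stem_left_nodes"]]
        right = [rg.observations[i] for i in rg.annotations["stem_right_nodes"]]
        assert left == right  # identical observation subsequence

    def test_stochastic_routes_overlap(self):
        rg = envs.make_route_environment("stochastic_routes", seed=0)
        assert rg.annotations["overlap_obs"] == [4, 5, 11, 12, 13, 5, 17]
        for key in ("green_overlap_nodes", "magenta_overlap_nodes"):
            assert [int(rg.observations[i]) for i in rg.annotations[key]] == [
                4, 5, 11, 12, 13, 5, 17
            ]

    def test_sampled_episode_obeys_successors(self):
        rg = envs.make_route_environment("stochastic_routes", seed=0)
        allowed = {
            (i, j) for i, succ in enumerate(rg.successors) for j, _ in succ
        }
        _, nodes = envs.sample_route(rg, int(rg.start_nodes[0]), seed=5)
        assert all((a, b) in allowed for a, b in zip(nodes[:-1], nodes[1:]))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            envs.make_route_environment("spiral", seed=0)


class TestRemappingSets:
    def test_rooms_are_permutations(self):
        rooms = envs.make_remapping_set("rooms", seed=1)
        assert len(rooms) == 5
        for room in rooms:
            assert sorted(room.grid.ravel().tolist()) == list(range(25))

    def test_mazes_use_six_symbols(self):
        mazes = envs.make_remapping_set("mazes", seed=1)
        assert len(mazes) == 5
        for maze in mazes:
            free = maze.grid[maze.grid != WALL]
            assert set(np.unique(free)) <= set(range(6))
            assert maze.n_obs == 6


class TestRandomWalk:
    def test_never_on_wall_and_reproducible(self):
        maze, _, _ = envs.make_hierarchical_maze(seed=0)
        seq1, pos1 = envs.random_walk(maze, 500, seed=3)
        seq2, pos2 = envs.random_walk(maze, 500, seed=3)
        assert np.array_equal(pos1, pos2)
        assert np.array_equal(seq1.observations, seq2.observations)
        assert all(maze.grid[r, c] != WALL for r, c in pos1)

    def test_two_cell_room_forced_alternation(self):
        room = GridEnvironment(np.array([[0, 1]]), 2)
        seq, pos = envs.random_walk(room, 10, seed=0)
        assert np.array_equal(np.abs(np.diff(seq.observations)), np.ones(9))

    def test_walk_kernel_uniform_over_legal_moves(self):
        """Chi-square goodness of fit of per-cell action frequencies."""
        from scipy import stats

        room = envs.make_room(6, 8, 4, seed=5)
        seq, pos = envs.random_walk(room, 100_000, seed=5)
        cells = {}
        for (r, c), a in zip(map(tuple, pos[:-1].tolist()), seq.actions):
            cells.setdefault((r, c), []).append(int(a))
        pvals = []
        for cell, actions in cells.items():
            legal = room.legal_actions(cell)
            counts = np.bincount(actions, minlength=4)[legal]
            if counts.sum() >= 200:
                pvals.append(stats.chisquare(counts).pvalue)
        # global test: combine per-cell p-values (Fisher)
        combined = stats.combine_pvalues(pvals).pvalue
        assert combined > 0.01

    def test_cover_time_six_by_eight(self):
        for seed in range(3):
            room = envs.make_room(6, 8, 18, seed=seed)
            _, pos = envs.random_walk(room, 50_000, seed=seed)
            assert len({tuple(p) for p in pos.tolist()}) == 48


class TestCorruption:
    def test_zero_probability_is_identity(self):
        seq, _ = envs.random_walk(envs.make_room(4, 4, 3, seed=0), 50, seed=0)
        noisy, mask = envs.corrupt_sequence(seq, 0.0, seed=1)
        assert np.array_equal(noisy.observations, seq.observations)
        assert not mask.any()

    def test_masked_positions_differ(self):
        seq, _ = envs.random_walk(envs.make_room(4, 4, 5, seed=0), 500, seed=0)
        noisy, mask = envs.corrupt_sequence(seq, 0.3, seed=1, n_obs=5)
        assert np.all(noisy.observations[mask] != seq.observations[mask])
        assert np.all(noisy.observations[~mask] == seq.observations[~mask])

    def test_corruption_count_binomial(self):
        from cscg.model import ActionObservationSequence

        seq = ActionObservationSequence(np.zeros(10_000, dtype=np.int64))
        _, mask = envs.corrupt_sequence(seq, 0.2, seed=2, n_obs=10)
        sd = np.sqrt(10_000 * 0.2 * 0.8)
        assert abs(mask.sum() - 2000) <= 3 * sd

    def test_invalid_probability(self):
        seq, _ = envs.random_walk(envs.make_room(4, 4, 3, seed=0), 10, seed=0)
        with pytest.raises(ValueError):
            envs.corrupt_sequence(seq, 1.0)
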