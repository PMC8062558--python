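"""Synthetic environments and the walkers that generate training data.

Everything here emulates the classic cognitive-map testbeds: aliased grid
rooms, pairs of overlapping rooms with a confounder patch, hierarchical mazes
of bridged rooms, an aliased modular graph, figure-eight and odor-sequence
route tasks, lap-running tracks, and sets of environments sharing observation
alphabets for remapping studies.  All generators are pure functions of their
seed.

Grid convention: row-major 0-based coordinates; ``-1`` marks a wall/blocked
cell; actions are ``0=up (-row), 1=right, 2=down, 3=left``.  Action semantics
are opaque to the learner — the agent only sees that action id k happened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import ActionObservationSequence

__all__ = [
    "WALL",
    "ACTIONS",
    "GridEnvironment",
    "RouteGraph",
    "make_room",
    "make_overlapping_rooms",
    "make_hierarchical_maze",
    "make_modular_graph",
    "make_lap_track",
    "make_route_environment",
    "make_remapping_set",
    "random_walk",
    "sample_route",
    "corrupt_sequence",
]

WALL = -1
# action id -> (d_row, d_col)
ACTIONS = np.array([(-1, 0), (0, 1), (1, 0), (0, -1)], dtype=np.int64)
N_GRID_ACTIONS = 4


@dataclass
class GridEnvironment:
    """A 2-D grid of observation symbols with walls; the agent moves in 4-space."""

    grid: np.ndarray
    n_obs: int
    name: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        free = self.grid != WALL
        if not free.any():
            raise ValueError("environment needs at least one non-wall cell")
        if self.grid[free].max() >= self.n_obs or self.grid[free].min() < 0:
            raise ValueError("grid symbols must lie in [0, n_obs)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def is_free(self, r: int, c: int) -> bool:
        h, w = self.grid.shape
        return 0 <= r < h and 0 <= c < w and self.grid[r, c] != WALL

    def free_cells(self) -> np.ndarray:
        return np.argwhere(self.grid != WALL)

    def legal_actions(self, pos) -> np.ndarray:
        r, c = pos
        return np.array(
            [k for k in range(N_GRID_ACTIONS)
             if self.is_free(r + ACTIONS[k, 0], c + ACTIONS[k, 1])],
            dtype=np.int64,
        )

    def step(self, pos, action: int):
        """Resulting cell, or None if the move is rejected (wall / out of bounds)."""
        r, c = pos
        nr, nc = r + ACTIONS[action, 0], c + ACTIONS[action, 1]
        return (int(nr), int(nc)) if self.is_free(nr, nc) else None

    def observation(self, pos) -> int:
        return int(self.grid[pos[0], pos[1]])

    def to_networkx(self):
        """Undirected grid graph over free cells (a planning/shortest-path oracle)."""
        import networkx as nx

        g = nx.Graph()
        for r, c in self.free_cells():
            g.add_node((int(r), int(c)))
            for k in range(N_GRID_ACTIONS):
                nxt = self.step((r, c), k)
                if nxt is not None:
                    g.add_edge((int(r), int(c)), nxt)
        return g

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "grid": self.grid.tolist(), "wall": WALL,
                 "n_obs": self.n_obs, "seed": self.seed},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GridEnvironment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["grid"]), d["n_obs"], d.get("name", ""), d.get("seed", 0))


@dataclass
class RouteGraph:
    """Positions with observations and (possibly stochastic) successor sets.

    ``successors[i]`` is a list of ``(next_node, probability)`` pairs summing to
    one, or empty for a terminal node.  ``start_nodes`` designates where route
    episodes begin.
    """

    observations: np.ndarray
    successors: list
    n_obs: int
    start_nodes: np.ndarray = field(default_factory=lambda: np.array([0]))
    name: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.int64)
        self.start_nodes = np.asarray(self.start_nodes, dtype=np.int64)
        for i, succ in enumerate(self.successors):
            if succ:
                total = sum(p for _, p in succ)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"successor probabilities of node {i} sum to {total}")

    @property
    def n_nodes(self) -> int:
        return int(self.observations.size)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "n_obs": self.n_obs,
                 "start_nodes": self.start_nodes.tolist(),
                 "nodes": [
                     {"obs": int(o), "successors": [{"to": int(t), "p": p} for t, p in s]}
                     for o, s in zip(self.observations, self.successors)
                 ]},
                fh,
            )


# ---------------------------------------------------------------------------
# Rooms
# ---------------------------------------------------------------------------

def _fill_with_coverage(n_cells: int, n_obs: int, rng) -> np.ndarray:
    """Random symbols with every symbol used at least once (when feasible)."""
    vals = rng.integers(0, n_obs, size=n_cells)
    if n_cells >= n_obs:
        forced = rng.permutation(n_cells)[:n_obs]
        vals[forced] = rng.permutation(n_obs)
    return vals


def make_room(
    height: int,
    width: int,
    n_obs: int,
    seed: int = 0,
    uniform_interior: bool = False,
) -> GridEnvironment:
    """An aliased rectangular room: few unique symbols scattered over many cells.

    With ``uniform_interior`` every non-border cell shares symbol 0 and border
    cells take the remaining symbols, emulating a featureless open room whose
    only distinct sensations occur near the walls.
    """
    if height < 1 or width < 1 or n_obs < 1:
        raise ValueError("dimensions and n_obs must be positive")
    if n_obs > height * width:
        raise ValueError("more symbols than cells")
    rng = np.random.default_rng(seed)
    if uniform_interior:
        grid = np.zeros((height, width), dtype=np.int64)
        border = np.ones((height, width), dtype=bool)
        if height > 2 and width > 2:
            border[1:-1, 1:-1] = False
        nb = int(border.sum())
        if n_obs > 1:
            vals = 1 + rng.integers(0, n_obs - 1, size=nb)
            if nb >= n_obs - 1:
                forced = rng.permutation(nb)[: n_obs - 1]
                vals[forced] = 1 + rng.permutation(n_obs - 1)
            grid[border] = vals
    else:
        grid = _fill_with_coverage(height * width, n_obs, rng).reshape(height, width)
    return GridEnvironment(grid, n_obs, name=f"room{height}x{width}", seed=seed)


def make_overlapping_rooms(seed: int = 0):
    """Two 8x6 rooms over 15 symbols sharing a 3x3 patch in their corners.

    The rooms are windows into one coherent global map: room 2 is offset
    diagonally so that room 1's bottom-right 3x3 corner and room 2's top-left
    3x3 corner are the same physical cells.  Room 1 additionally contains a
    disjoint copy of the shared patch (the confounder), so stitching the rooms
    requires temporal context rather than local template matching.  Returns
    ``(room1, room2, annotations)`` with per-room patch coordinates.
    """
    rng = np.random.default_rng(seed)
    h, w, E, P = 8, 6, 15, 3
    world = _fill_with_coverage((h + h - P) * (w + w - P), E, rng).reshape(
        h + h - P, w + w - P
    )
    g1 = world[0:h, 0:w].copy()
    g2 = world[h - P:2 * h - P, w - P:2 * w - P].copy()
    # confounder copy in room 1's interior, away from the shared corner; an
    # interior placement keeps its movement context distinct from the corner
    # patch so only temporal context — not local appearance — separates them
    g1[1:1 + P, 1:1 + P] = world[h - P:h, w - P:w]
    annotations = {
        "patch_size": P,
        "overlap_room1": (h - P, w - P),
        "overlap_room2": (0, 0),
        "confounder_room1": (1, 1),
    }
    room1 = GridEnvironment(g1, E, name="overlap_room1", seed=seed)
    room2 = GridEnvironment(g2, E, name="overlap_room2", seed=seed)
    return room1, room2, annotations


def make_hierarchical_maze(
    seed: int = 0, rooms_per_side: int = 4, room_size: int = 5
):
    """Square tiling of aliased rooms joined by single-cell bridges.

    Rooms draw observations from 12 aliased symbols (ids 0-11); bridge cells
    carry the dedicated symbol 12.  The bridge layout carries a second level of
    structure: all four bridges inside every 2x2 block of rooms are present,
    but adjacent blocks are joined by exactly one bridge, so the block ("hyper-
    room") partition is recoverable from connectivity alone.

    Returns ``(env, room_labels, hyper_labels)``; labels are per-cell arrays
    with the room / hyper-room index, ``-2`` on bridges and ``-1`` on walls.
    """
    if rooms_per_side < 2:
        raise ValueError("rooms_per_side must be >= 2")
    rng = np.random.default_rng(seed)
    R, S = rooms_per_side, room_size
    side = R * S + (R - 1)
    grid = np.full((side, side), WALL, dtype=np.int64)
    room_labels = np.full((side, side), -1, dtype=np.int64)
    hyper_labels = np.full((side, side), -1, dtype=np.int64)
    hyper_side = (R + 1) // 2
    n_room_cells = R * R * S * S
    # i.i.d. symbol draws, then rebalanced so no symbol's multiplicity exceeds
    # its expected share by much — a run of bad luck would otherwise demand
    # more clones of one symbol than any fixed allocation provides
    symbols = rng.integers(0, 12, size=n_room_cells)
    cap = int(np.ceil(n_room_cells / 12 * 1.1))
    counts = np.bincount(symbols, minlength=12)
    for s in range(12):
        while counts[s] > cap:
            donate = rng.choice(np.flatnonzero(symbols == s))
            target = int(np.argmin(counts))
            symbols[donate] = target
            counts[s] -= 1
            counts[target] += 1
    cursor = 0
    for r in range(R):
        for c in range(R):
            r0, c0 = r * (S + 1), c * (S + 1)
            grid[r0:r0 + S, c0:c0 + S] = symbols[cursor:cursor + S * S].reshape(S, S)
            cursor += S * S
            room_labels[r0:r0 + S, c0:c0 + S] = r * R + c
            hyper_labels[r0:r0 + S, c0:c0 + S] = (r // 2) * hyper_side + (c // 2)
    mid = S // 2

    def same_block(ra, ca, rb, cb):
        return (ra // 2, ca // 2) == (rb // 2, cb // 2)

    # within a 2x2 block, adjacent rooms are joined by two bridge cells;
    # adjacent blocks share a single bridge — the denser in-block wiring is
    # the second level of structure the abstraction is meant to discover
    def bridge_offsets(internal: bool):
        return (mid - 1, mid + 1) if internal else (mid,)

    for r in range(R):
        for c in range(R - 1):  # horizontal bridges between (r,c) and (r,c+1)
            internal = same_block(r, c, r, c + 1)
            if internal or r % 2 == 0:
                for off in bridge_offsets(internal):
                    rr = r * (S + 1) + off
                    cc = c * (S + 1) + S
                    grid[rr, cc] = 12
                    room_labels[rr, cc] = -2
                    hyper_labels[rr, cc] = -2
    for r in range(R - 1):
        for c in range(R):  # vertical bridges between (r,c) and (r+1,c)
            internal = same_block(r, c, r + 1, c)
            if internal or c % 2 == 0:
                for off in bridge_offsets(internal):
                    rr = r * (S + 1) + S
                    cc = c * (S + 1) + off
                    grid[rr, cc] = 12
                    room_labels[rr, cc] = -2
                    hyper_labels[rr, cc] = -2
    env = GridEnvironment(grid, 13, name=f"hiermaze{R}x{R}", seed=seed)
    return env, room_labels, hyper_labels


# ---------------------------------------------------------------------------
# Graph and route environments
# ---------------------------------------------------------------------------

def make_modular_graph(seed: int = 0):
    """Aliased three-cluster modular graph: 15 nodes, every node of degree 4.

    Three five-node clusters arranged in a ring; within a cluster the three
    internal nodes connect to everything in the cluster while the two boundary
    nodes connect to the internal nodes and to one boundary node of the next
    cluster.  Each cluster reuses the same five observation labels (in a
    seeded, cluster-specific permutation), so identical symbols occur in
    different clusters and instantaneous observations do not identify nodes.

    Returns ``(route_graph, communities)`` with the ground-truth cluster index
    per node.
    """
    rng = np.random.default_rng(seed)
    n_clusters, size = 3, 5
    n = n_clusters * size
    adj = [set() for _ in range(n)]
    for c in range(n_clusters):
        base = c * size
        ids = list(range(base, base + size))
        for i in ids:
            for j in ids:
                if i < j and not ({i, j} == {base, base + size - 1}):
                    adj[i].add(j)
                    adj[j].add(i)
        nxt = ((c + 1) % n_clusters) * size
        adj[base + size - 1].add(nxt)
        adj[nxt].add(base + size - 1)
    obs = np.zeros(n, dtype=np.int64)
    for c in range(n_clusters):
        obs[c * size:(c + 1) * size] = rng.permutation(size)
    successors = [
        [(j, 1.0 / len(adj[i])) for j in sorted(adj[i])] for i in range(n)
    ]
    communities = np.repeat(np.arange(n_clusters), size)
    graph = RouteGraph(
        obs, successors, n_obs=size, start_nodes=np.arange(n),
        name="modular_graph", annotations={"communities": communities},
    )
    return graph, communities


def make_lap_track(elongation: int = 0):
    """The four-lap track: start, four repetitions of positions 1-12, reward.

    Observation ids: corridor positions are symbols 0-11, the start cue is 12
    and the goal/reward is 13 (a 14-symbol alphabet).  With ``elongation > 0``
    each corridor observation is repeated ``1 + elongation`` times — the way a
    physically stretched corridor re-emits the same sensation — which changes
    nothing else about the sequence.  Returns ``(sequence, annotations)`` where
    the annotations give the lap number and corridor position of every step
    (-1 outside the corridor).
    """
    if elongation < 0:
        raise ValueError("elongation must be >= 0")
    rep = 1 + elongation
    obs = [12]
    lap = [-1]
    pos = [-1]
    for l in range(4):
        for p in range(12):
            obs.extend([p] * rep)
            lap.extend([l] * rep)
            pos.extend([p] * rep)
    obs.append(13)
    lap.append(-1)
    pos.append(-1)
    seq = ActionObservationSequence(
        np.asarray(obs), np.zeros(len(obs) - 1, dtype=np.int64)
    )
    annotations = {
        "lap": np.asarray(lap), "position": np.asarray(pos),
        "n_obs": 14, "start_symbol": 12, "reward_symbol": 13, "n_laps": 4,
    }
    return seq, annotations


def make_route_environment(kind: str, seed: int = 0) -> RouteGraph:
    """Route tasks with overlapping segments.

    ``tmaze_fig8``: an alternating figure-eight T-maze — the stem (observations
    0-3) is traversed on every trial, followed by the left arm (4-8) or the
    right arm (9-13) in strict alternation, so the same stem sensations occur
    in two different route contexts.

    ``odor_sequences``: two odor sequences sharing their middle three odors,
    chosen uniformly at random per trial.

    ``stochastic_routes``: two routes to a common destination, each with
    stochastic sub-paths, overlapping in the seven-location middle segment with
    observations 4-5-11-12-13-5-17.
    """
    if kind == "tmaze_fig8":
        # Two aliased copies of the stem: one entered before a left turn, one
        # before a right turn; arms feed the opposite stem copy (alternation).
        stem = [0, 1, 2, 3]
        left_arm = [4, 5, 6, 7, 8]
        right_arm = [9, 10, 11, 12, 13]
        obs = stem + left_arm + stem + right_arm
        nL, nA = len(stem), len(left_arm)
        succ = [[] for _ in range(len(obs))]
        for i in range(len(obs)):
            succ[i] = [((i + 1) % len(obs), 1.0)]
        stem_left = list(range(0, nL))                       # stem before left turn
        left_ids = list(range(nL, nL + nA))
        stem_right = list(range(nL + nA, nL + nA + nL))      # stem before right turn
        right_ids = list(range(nL + nA + nL, len(obs)))
        return RouteGraph(
            np.asarray(obs), succ, n_obs=14, start_nodes=np.array([0]),
            name="tmaze_fig8",
            annotations={
                "stem_obs": stem, "stem_left_nodes": stem_left,
                "stem_right_nodes": stem_right, "left_arm_nodes": left_ids,
                "right_arm_nodes": right_ids,
            },
        )
    if kind == "odor_sequences":
        # inter-trial cue 7, then one of two sequences sharing odors 2-3-4.
        seq1 = [0, 2, 3, 4, 5]
        seq2 = [1, 2, 3, 4, 6]
        obs = [7] + seq1 + seq2
        succ = [[] for _ in range(len(obs))]
        succ[0] = [(1, 0.5), (1 + len(seq1), 0.5)]
        for i in range(1, len(seq1)):
            succ[i] = [(i + 1, 1.0)]
        succ[len(seq1)] = [(0, 1.0)]
        for i in range(1 + len(seq1), len(obs) - 1):
            succ[i] = [(i + 1, 1.0)]
        succ[len(obs) - 1] = [(0, 1.0)]
        return RouteGraph(
            np.asarray(obs), succ, n_obs=8, start_nodes=np.array([0]),
            name="odor_sequences",
            annotations={"shared_obs": [2, 3, 4],
                         "route1_nodes": list(range(1, 6)),
                         "route2_nodes": list(range(6, 11))},
        )
    if kind == "stochastic_routes":
        overlap = [4, 5, 11, 12, 13, 5, 17]
        obs: list[int] = []
        succ: list[list] = []

        def add(o):
            obs.append(o)
            succ.append([])
            return len(obs) - 1

        # green route: start 0, stochastic pre-paths, overlap, exit 14-15, dest 2
        g0 = add(0)
        ga = [add(6), add(7)]
        gb = [add(8), add(9)]
        g_over = [add(o) for o in overlap]
        g_post = [add(14), add(15)]
        g_dest = add(2)
        succ[g0] = [(ga[0], 0.5), (gb[0], 0.5)]
        succ[ga[0]] = [(ga[1], 1.0)]
        succ[gb[0]] = [(gb[1], 1.0)]
        succ[ga[1]] = [(g_over[0], 1.0)]
        succ[gb[1]] = [(g_over[0], 1.0)]
        for i in range(len(g_over) - 1):
            succ[g_over[i]] = [(g_over[i + 1], 1.0)]
        succ[g_over[-1]] = [(g_post[0], 1.0)]
        succ[g_post[0]] = [(g_post[1], 1.0)]
        succ[g_post[1]] = [(g_dest, 1.0)]
        # magenta route: start 1, its own stochastic pre-paths, aliased overlap,
        # exit 8-6, same destination observation 2
        m0 = add(1)
        ma = [add(7), add(10)]
        mb = [add(9), add(16)]
        m_over = [add(o) for o in overlap]
        m_post = [add(8), add(6)]
        m_dest = add(2)
        succ[m0] = [(ma[0], 0.5), (mb[0], 0.5)]
        succ[ma[0]] = [(ma[1], 1.0)]
        succ[mb[0]] = [(mb[1], 1.0)]
        succ[ma[1]] = [(m_over[0], 1.0)]
        succ[mb[1]] = [(m_over[0], 1.0)]
        for i in range(len(m_over) - 1):
            succ[m_over[i]] = [(m_over[i + 1], 1.0)]
        succ[m_over[-1]] = [(m_post[0], 1.0)]
        succ[m_post[0]] = [(m_post[1], 1.0)]
        succ[m_post[1]] = [(m_dest, 1.0)]
        return RouteGraph(
            np.asarray(obs), succ, n_obs=18,
            start_nodes=np.array([g0, m0]),
            name="stochastic_routes",
            annotations={
                "overlap_obs": overlap,
                "green_start": g0, "magenta_start": m0,
                "green_overlap_nodes": g_over, "magenta_overlap_nodes": m_over,
                "green_nodes": list(range(g0, g_dest + 1)),
                "magenta_nodes": list(range(m0, m_dest + 1)),
                "green_post": [obs[g_post[0]], obs[g_post[1]]],
                "magenta_post": [obs[m_post[0]], obs[m_post[1]]],
            },
        )
    raise ValueError(f"unknown route environment kind {kind!r}")


def _loop_track(height: int, width: int) -> np.ndarray:
    """Rectangular ring over the 6-symbol maze alphabet.

    Corners get orientation symbols 0-3 (NW, NE, SE, SW); horizontal arms share
    symbol 4 and vertical arms symbol 5.
    """
    grid = np.full((height, width), WALL, dtype=np.int64)
    grid[0, 1:-1] = 4
    grid[-1, 1:-1] = 4
    grid[1:-1, 0] = 5
    grid[1:-1, -1] = 5
    grid[0, 0], grid[0, -1] = 0, 1
    grid[-1, -1], grid[-1, 0] = 2, 3
    return grid


def make_remapping_set(kind: str, seed: int = 0) -> list[GridEnvironment]:
    """Five environments sharing one observation alphabet.

    ``rooms``: five 5x5 rooms, each an independent random permutation of the
    25 symbols — same sensations, different arrangements.  ``mazes``: five
    closed-loop tracks of different proportions over six symbols (four corner
    types plus horizontal/vertical arm), structurally similar to each other and
    with low walk branching.
    """
    rng = np.random.default_rng(seed)
    if kind == "rooms":
        return [
            GridEnvironment(
                rng.permutation(25).reshape(5, 5), 25, name=f"room{i}", seed=seed
            )
            for i in range(5)
        ]
    if kind == "mazes":
        shapes = [(5, 5), (4, 8), (8, 4), (3, 7), (7, 5)]
        return [
            GridEnvironment(_loop_track(h, w), 6, name=f"maze{i}", seed=seed)
            for i, (h, w) in enumerate(shapes)
        ]
    raise ValueError(f"unknown remapping set kind {kind!r}")


# ---------------------------------------------------------------------------
# Walkers and corruption
# ---------------------------------------------------------------------------

def random_walk(env, n_steps: int, seed: int = 0, start=None):
    """Uniform random walk; never takes an action that would leave the world.

    Returns ``(sequence, positions)`` where the sequence holds ``n_steps``
    observations and ``n_steps - 1`` actions.  For grid environments positions
    is an (N, 2) array of cells; for route graphs it is the node-id trace and
    the recorded action is always 0.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(env, GridEnvironment):
        if start is None:
            free = env.free_cells()
            start = tuple(free[rng.integers(len(free))])
        pos = (int(start[0]), int(start[1]))
        if not env.is_free(*pos):
            raise ValueError(f"start cell {pos} is blocked")
        if env.legal_actions(pos).size == 0:
            raise ValueError(f"no legal move from start cell {pos}")
        obs = np.zeros(n_steps, dtype=np.int64)
        acts = np.zeros(max(n_steps - 1, 0), dtype=np.int64)
        positions = np.zeros((n_steps, 2), dtype=np.int64)
        obs[0] = env.observation(pos)
        positions[0] = pos
        for n in range(n_steps - 1):
            legal = env.legal_actions(pos)
            k = int(legal[rng.integers(legal.size)])
            pos = env.step(pos, k)
            acts[n] = k
            obs[n + 1] = env.observation(pos)
            positions[n + 1] = pos
        seq = ActionObservationSequence(obs, acts if n_steps > 1 else None)
        return seq, positions
    if isinstance(env, RouteGraph):
        if start is None:
            start = int(env.start_nodes[rng.integers(env.start_nodes.size)])
        node = int(start)
        obs = [int(env.observations[node])]
        nodes = [node]
        for _ in range(n_steps - 1):
            succ = env.successors[node]
            if not succ:
                break
            targets = np.array([t for t, _ in succ])
            probs = np.array([p for _, p in succ])
            node = int(targets[rng.choice(len(succ), p=probs)])
            nodes.append(node)
            obs.append(int(env.observations[node]))
        actions = np.zeros(len(obs) - 1, dtype=np.int64) if len(obs) > 1 else None
        return ActionObservationSequence(np.asarray(obs), actions), np.asarray(nodes)
    raise TypeError(f"unsupported environment type {type(env).__name__}")


def sample_route(env: RouteGraph, start_node: int, seed: int = 0, max_steps: int = 1000):
    """One episode from ``start_node`` until a terminal node (empty successors)."""
    return random_walk(env, max_steps, seed=seed, start=start_node)


def corrupt_sequence(
    seq: ActionObservationSequence, p: float, seed: int = 0, n_obs: int | None = None
):
    """Independently replace each symbol w.p. ``p`` by a uniform wrong symbol.

    Returns ``(noisy_sequence, mask)``; every masked position is guaranteed to
    differ from the original.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("corruption probability must lie in [0, 1)")
    E = int(seq.observations.max()) + 1 if n_obs is None else n_obs
    rng = np.random.default_rng(seed)
    obs = seq.observations.copy()
    mask = rng.random(obs.size) < p
    if E > 1:
        draws = rng.integers(0, E - 1, size=obs.size)
        draws[draws >= obs] += 1  # uniform over the E-1 wrong symbols
        obs[mask] = draws[mask]
    else:
        mask[:] = False
    return ActionObservationSequence(obs, None if seq.actions is None else seq.actions.copy()), mask
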