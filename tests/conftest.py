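"""Shared fixtures and independent oracles.

The enumeration oracle computes likelihoods, posteriors and MAP paths by
summing / maximizing over every clone path explicitly, so it shares no code
with the message-passing implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from cscg.model import ActionObservationSequence, CloneAllocation, CSCGModel, create_model


# ---------------------------------------------------------------------------
# Enumeration oracle (brute force over clone paths)
# ---------------------------------------------------------------------------

def enumerate_paths(model: CSCGModel, seq: ActionObservationSequence):
    """All clone paths consistent with the observations, with joint probabilities."""
    off = model.allocation.offsets
    x = seq.observations
    a = seq.effective_actions()
    supports = [range(off[xi], off[xi + 1]) for xi in x]
    paths, probs = [], []
    for p in product(*supports):
        pr = model.prior[p[0]]
        for n in range(len(x) - 1):
            pr *= model.transitions[p[n], a[n], p[n + 1]]
        paths.append(p)
        probs.append(pr)
    return paths, np.asarray(probs)


def oracle_loglik(model, seq) -> float:
    _, probs = enumerate_paths(model, seq)
    total = probs.sum()
    return float(np.log(total)) if total > 0 else -np.inf


def oracle_gammas(model, seq) -> np.ndarray:
    """(N, H) smoothed posteriors by explicit summation."""
    paths, probs = enumerate_paths(model, seq)
    N, H = len(seq), model.n_states
    g = np.zeros((N, H))
    for p, pr in zip(paths, probs):
        for n, z in enumerate(p):
            g[n, z] += pr
    return g / probs.sum()


def oracle_filtered(model, seq) -> np.ndarray:
    """(N, H) filtered posteriors: enumerate prefixes."""
    N, H = len(seq), model.n_states
    out = np.zeros((N, H))
    for n in range(N):
        prefix = ActionObservationSequence(
            seq.observations[: n + 1],
            None if seq.actions is None else seq.actions[:n],
        )
        paths, probs = enumerate_paths(model, prefix)
        for p, pr in zip(paths, probs):
            out[n, p[-1]] += pr
        out[n] /= out[n].sum()
    return out


def oracle_xi_counts(model, seq) -> np.ndarray:
    """(H, n_actions, H) expected transition counts by explicit summation."""
    paths, probs = enumerate_paths(model, seq)
    a = seq.effective_actions()
    counts = np.zeros_like(model.transitions)
    Z = probs.sum()
    for p, pr in zip(paths, probs):
        for n in range(len(p) - 1):
            counts[p[n], a[n], p[n + 1]] += pr / Z
    return counts


def oracle_viterbi_logprob(model, seq) -> float:
    _, probs = enumerate_paths(model, seq)
    best = probs.max()
    return float(np.log(best)) if best > 0 else -np.inf


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def random_tiny_model(rng: np.random.Generator):
    """A random CSCG with at most 6 states, for oracle comparisons."""
    E = int(rng.integers(2, 4))
    clones = [int(rng.integers(1, 3)) for _ in range(E)]
    while sum(clones) > 6:
        clones[int(rng.integers(E))] = 1
    allocation = CloneAllocation(clones)
    n_actions = int(rng.integers(1, 3))
    return create_model(allocation, n_actions, seed=int(rng.integers(2**31)))


def random_sequence(model: CSCGModel, rng: np.random.Generator, max_len: int = 8):
    N = int(rng.integers(2, max_len + 1))
    x = rng.integers(0, model.n_obs, size=N)
    a = rng.integers(0, model.n_actions, size=N - 1)
    return ActionObservationSequence(x, a)


def cycle_model(n_symbols: int = 3, n_actions: int = 1) -> CSCGModel:
    """Deterministic cycle 0 -> 1 -> ... -> E-1 -> 0, one clone per symbol."""
    allocation = CloneAllocation.uniform(n_symbols, 1)
    H = n_symbols
    T = np.zeros((H, n_actions, H))
    for i in range(H):
        T[i, 0, (i + 1) % H] = 1.0
    prior = np.zeros(H)
    prior[0] = 1.0
    return CSCGModel(allocation, n_actions, prior, T)


def perfect_room_model(env) -> tuple[CSCGModel, dict]:
    """Ground-truth CSCG of a grid environment: one clone per cell.

    Returns the model and the cell -> state mapping.  Transitions are
    deterministic given the action, with the action marginal uniform over the
    cell's legal moves (the random-walk kernel).
    """
    from cscg import envs as envs_mod

    cells = [tuple(c) for c in env.free_cells()]
    symbols = np.array([env.observation(c) for c in cells])
    order = np.argsort(symbols, kind="stable")
    cells = [cells[i] for i in order]
    symbols = symbols[order]
    clones_per_obs = np.bincount(symbols, minlength=env.n_obs)
    clones_per_obs = np.maximum(clones_per_obs, 1)
    allocation = CloneAllocation(clones_per_obs)
    state_of = {c: i for i, c in enumerate(cells)}
    H = allocation.n_states
    T = np.zeros((H, 4, H))
    for c, i in state_of.items():
        legal = env.legal_actions(c)
        for k in legal:
            j = state_of[env.step(c, int(k))]
            T[i, int(k), j] = 1.0 / legal.size
    prior = np.full(H, 1.0 / H)
    model = CSCGModel(allocation, 4, prior, T)
    model.validate()
    return model, state_of


def identifiable_small_cscg() -> CSCGModel:
    """An 8-state, 2-action CSCG with clearly distinguished clones.

    Each action follows its own permutation over the clones (with 10% spread),
    and the two actions have asymmetric state-conditional probabilities, so
    the generator is identifiable up to within-symbol clone permutation.
    """
    allocation = CloneAllocation.uniform(4, 2)
    H = allocation.n_states
    p0 = np.array([2, 4, 5, 6, 7, 1, 3, 0])  # action 0 successor permutation
    p1 = np.array([3, 5, 0, 7, 1, 2, 6, 4])  # action 1 successor permutation
    T = np.full((H, 2, H), 0.1 / (2 * H))
    for z in range(H):
        T[z, 0, p0[z]] += 0.9 * 0.6
        T[z, 1, p1[z]] += 0.9 * 0.4
    T /= T.reshape(H, -1).sum(axis=1)[:, None, None]
    model = CSCGModel(allocation, 2, np.full(H, 1.0 / H), T)
    model.validate()
    return model


def recovery_tv(true: CSCGModel, fitted: CSCGModel) -> float:
    """Best max-row total-variation distance over within-symbol clone relabelings."""
    from itertools import product as _product

    n_actions = true.n_actions
    best = np.inf
    for perms in _product(*[[(0, 1), (1, 0)]] * true.n_obs):
        mapping = np.concatenate(
            [np.asarray(p) + 2 * j for j, p in enumerate(perms)]
        )
        P = fitted.transitions[np.ix_(mapping, np.arange(n_actions), mapping)]
        tv = 0.5 * np.abs(P - true.transitions).reshape(
            true.n_states, -1
        ).sum(axis=1).max()
        best = min(best, tv)
    return float(best)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cycle():
    return cycle_model(3)
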