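"""Learning algorithms for CSCGs.

Batch EM (Baum-Welch with the block-sparse clone structure), Dirichlet-MAP
smoothing with a pseudocount, Viterbi (hard-EM) refinement, emission-only
relearning for schema transfer, and an adaptive online EM with exponential
forgetting.

The E-step exploits the clone structure: the forward/backward recursions touch
only the submatrix ``T(C(x_n), a_n, C(x_{n+1}))`` at each step, so one EM sweep
costs O(M^2 N) for M clones per symbol, independent of the alphabet size.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ActionObservationSequence, CloneAllocation, CSCGModel, create_model

__all__ = [
    "EMConfig",
    "MessageTrace",
    "SufficientStats",
    "OnlineEMState",
    "forward_backward",
    "loglikelihood",
    "e_step",
    "m_step",
    "em_fit",
    "viterbi_train",
    "fit_two_phase",
    "memorize",
    "split_refine",
    "split_merge_refine",
    "used_states",
    "prune_model",
    "learn_emission",
    "online_em_update",
    "forward_op_count",
]


@dataclass
class EMConfig:
    """Knobs for EM and Viterbi training.

    ``pseudocount`` is the Dirichlet-prior constant kappa added to every
    transition count in the M-step; ``tol`` is the relative log-likelihood
    improvement below which training stops; ``n_restarts`` fits from that many
    random initializations and keeps the best penalized log-likelihood.

    ``normalization`` selects the EM dynamics.  With ``"conditional"`` (the
    default) the E-step runs on the action-conditioned tensor P(z' | z, a) —
    actions are conditioned on, not predicted — which consolidates redundant
    clones markedly better on navigation data; the fitted model is converted
    back to the joint P(z', a | z) parameterization through the empirical
    per-state action frequencies, so the stored tensor always satisfies the
    joint normalization.  ``"joint"`` optimizes the joint likelihood directly.
    """

    max_iters: int = 100
    pseudocount: float = 0.0
    tol: float = 1e-6
    n_restarts: int = 1
    seed: int = 0
    normalization: str = "conditional"
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0 or self.pseudocount < 0:
            raise ValueError("tol and pseudocount must be non-negative")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.normalization not in ("conditional", "joint"):
            raise ValueError("normalization must be 'conditional' or 'joint'")
        if self.dtype not in ("float64", "float32"):
            raise ValueError("dtype must be 'float64' or 'float32'")


@dataclass
class MessageTrace:
    """Forward/backward messages of one sequence, block-restricted and scaled.

    ``alphas[n]`` / ``betas[n]`` are padded rows; only the first M_{x_n} entries
    are meaningful (use :meth:`alpha` / :meth:`beta` for trimmed views).
    ``loglik`` equals the sum of log normalizers.
    """

    alphas: np.ndarray
    betas: np.ndarray
    scales: np.ndarray
    loglik: float
    observations: np.ndarray
    offsets: np.ndarray

    def _width(self, n: int) -> int:
        x = self.observations[n]
        return int(self.offsets[x + 1] - self.offsets[x])

    def alpha(self, n: int) -> np.ndarray:
        return self.alphas[n, : self._width(n)]

    def beta(self, n: int) -> np.ndarray:
        return self.betas[n, : self._width(n)]

    def gamma(self, n: int) -> np.ndarray:
        """Smoothed posterior over the clones of x_n (sums to 1)."""
        g = self.alpha(n) * self.beta(n)
        return g / g.sum()


@dataclass
class SufficientStats:
    """Expected-count accumulators, additive across independent sequences."""

    counts: np.ndarray          # (H, n_actions, H) accumulated xi
    prior_counts: np.ndarray    # (H,) accumulated gamma(1)
    allocation: CloneAllocation
    n_actions: int
    n_sequences: int = 0
    loglik: float = 0.0
    gammas: list = field(default_factory=list)  # per-sequence MessageTrace refs

    def add(self, other: "SufficientStats") -> "SufficientStats":
        self.counts += other.counts
        self.prior_counts += other.prior_counts
        self.n_sequences += other.n_sequences
        self.loglik += other.loglik
        self.gammas.extend(other.gammas)
        return self


def _prep(model: CSCGModel, seq: ActionObservationSequence):
    seq.validate_against(model.n_obs, model.n_actions)
    x = seq.observations
    a = seq.effective_actions()
    if seq.actions is None and model.n_actions > 1:
        raise ValueError(
            "sequence has no actions but the model has more than one action; "
            "train an action-free cloned HMM with n_actions=1"
        )
    return x, a, model.allocation.offsets


def forward_backward(model: CSCGModel, seq: ActionObservationSequence) -> MessageTrace:
    """Exact scaled forward/backward messages; loglik = log P(x, a).

    A zero-probability sequence (possible only with zero pseudocount) is
    returned with ``loglik = -inf`` rather than raising.
    """
    x, a, offsets = _prep(model, seq)
    N = x.size
    mmax = int(model.allocation.clones_per_obs.max())
    alphas = np.zeros((N, mmax))
    betas = np.zeros((N, mmax))
    scales = np.zeros(N)
    loglik = _kernels.forward(model.transitions, model.prior, offsets, x, a, alphas, scales)
    if np.isfinite(loglik):
        _kernels.backward(model.transitions, offsets, x, a, scales, betas)
    return MessageTrace(alphas, betas, scales, float(loglik), x, offsets)


def loglikelihood(model: CSCGModel, seq: ActionObservationSequence) -> float:
    x, a, offsets = _prep(model, seq)
    mmax = int(model.allocation.clones_per_obs.max())
    alphas = np.zeros((x.size, mmax))
    scales = np.zeros(x.size)
    return float(
        _kernels.forward(model.transitions, model.prior, offsets, x, a, alphas, scales)
    )


def e_step(model: CSCGModel, seq: ActionObservationSequence) -> SufficientStats:
    """Expected transition counts xi_{ikj} and gamma(1) for one sequence."""
    x, a, offsets = _prep(model, seq)
    trace = forward_backward(model, seq)
    H = model.n_states
    counts = np.zeros((H, model.n_actions, H))
    prior_counts = np.zeros(H)
    if not np.isfinite(trace.loglik):
        raise ValueError("sequence has zero probability under the model (loglik=-inf)")
    _kernels.accumulate_counts(
        model.transitions, offsets, x, a,
        trace.alphas, trace.betas, trace.scales, counts, prior_counts,
    )
    return SufficientStats(
        counts, prior_counts, model.allocation, model.n_actions,
        n_sequences=1, loglik=trace.loglik, gammas=[trace],
    )


def m_step(
    stats: SufficientStats,
    pseudocount: float = 0.0,
    fallback: CSCGModel | None = None,
) -> CSCGModel:
    """Row-normalize smoothed counts into a new model.

    ``T(i,k,j) = (kappa + counts_ikj) / sum_{k',j'} (kappa + counts_ik'j')``;
    the prior is re-estimated from the (equally smoothed) gamma(1) counts.
    With ``pseudocount=0`` a state with no expected outgoing counts is
    degenerate: its row is copied from ``fallback`` if given, otherwise an
    error is raised.
    """
    if np.any(stats.counts < 0):
        raise ValueError("negative expected counts")
    H = stats.allocation.n_states
    T = stats.counts + pseudocount
    row_sums = T.reshape(H, -1).sum(axis=1)
    dead = row_sums <= 0
    if np.any(dead):
        if fallback is None:
            raise ValueError(
                f"{int(dead.sum())} states have all-zero counts and pseudocount=0 "
                "(degenerate rows); pass a fallback model or use pseudocount > 0"
            )
        T[dead] = fallback.transitions[dead]
        row_sums[dead] = 1.0
    T /= row_sums[:, None, None]
    prior = stats.prior_counts + pseudocount
    ps = prior.sum()
    if ps <= 0:
        if fallback is None:
            raise ValueError("all-zero prior counts with pseudocount=0")
        prior = fallback.prior.copy()
    else:
        prior = prior / ps
    return CSCGModel(stats.allocation, stats.n_actions, prior, T)


def _penalty(T: np.ndarray, pi: np.ndarray, kappa: float) -> float:
    """log of the (unnormalized) Dirichlet prior: kappa * (sum log T + sum log pi)."""
    if kappa == 0.0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(kappa * np.sum(np.log(T)) + kappa * np.sum(np.log(pi)))


def _conditionalize(T: np.ndarray) -> np.ndarray:
    """P(z' | z, a) from a joint (or already conditional) tensor."""
    rs = T.sum(axis=2, keepdims=True)
    safe = np.where(rs > 0, rs, 1.0)
    H = T.shape[0]
    return np.where(rs > 0, T / safe, 1.0 / H)


def _normalize_counts(counts: np.ndarray, kappa: float, normalization: str) -> np.ndarray:
    sm = counts + kappa
    if normalization == "joint":
        denom = sm.reshape(sm.shape[0], -1).sum(axis=1)[:, None, None]
    else:
        denom = sm.sum(axis=2, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, sm / safe, 0.0)


def _joint_from_counts(
    counts: np.ndarray, kappa: float, fallback_T: np.ndarray
) -> np.ndarray:
    """Joint M-step of the accumulated counts, with fallback rows for dead states."""
    H = counts.shape[0]
    T = counts + kappa
    rs = T.reshape(H, -1).sum(axis=1)
    dead = rs <= 0
    if np.any(dead):
        T[dead] = fallback_T[dead]
        rs[dead] = 1.0
    return T / rs[:, None, None]


def _bigram_groups(seq: ActionObservationSequence):
    """Steps grouped by the (x_n, a_n, x_{n+1}) triple they share.

    Every step of a group touches the same transition block, so the group's
    expected-count contributions collapse into one small matrix product; the
    grouping depends only on the data and is computed once per fit.
    """
    x = seq.observations
    a = seq.effective_actions()
    keys = np.stack([x[:-1], a, x[1:]], axis=1)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(
        np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    ) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [keys.shape[0]]))
    groups = [
        (tuple(sorted_keys[s]), order[s:e]) for s, e in zip(starts, stops)
    ]
    bidx = np.empty(keys.shape[0], dtype=np.int64)
    for g, (_, steps) in enumerate(groups):
        bidx[steps] = g
    return groups, bidx


def _raw_estep(T, pi, offsets, mmax, seqs, groups_per_seq):
    """Counts, prior counts and total loglik of ``seqs`` under raw arrays.

    Forward/backward messages come from the sequential kernels; the xi-count
    accumulation is batched per observation bigram (one GEMM per group), which
    is what keeps long-sequence EM fast.
    """
    H = T.shape[0]
    counts = np.zeros_like(T)
    prior_counts = np.zeros(H, dtype=T.dtype)
    total_ll = 0.0
    for seq, (groups, bidx) in zip(seqs, groups_per_seq):
        x = seq.observations
        a = seq.effective_actions()
        N = x.size
        alphas = np.zeros((N, mmax), dtype=T.dtype)
        betas = np.zeros((N, mmax), dtype=T.dtype)
        scales = np.zeros(N, dtype=T.dtype)
        if N >= 2:
            blocks = np.zeros((len(groups), mmax, mmax), dtype=T.dtype)
            for g, ((xi, k, xj), _steps) in enumerate(groups):
                mi = offsets[xi + 1] - offsets[xi]
                mj = offsets[xj + 1] - offsets[xj]
                blocks[g, :mi, :mj] = T[
                    offsets[xi]:offsets[xi] + mi, k, offsets[xj]:offsets[xj] + mj
                ]
            ll = _kernels.forward_blocks(blocks, bidx, pi, offsets, x, a, alphas, scales)
            if not np.isfinite(ll):
                raise ValueError("sequence has zero probability under the model")
            _kernels.backward_blocks(blocks, bidx, offsets, x, a, scales, betas)
        else:
            ll = _kernels.forward(T, pi, offsets, x, a, alphas, scales)
            if not np.isfinite(ll):
                raise ValueError("sequence has zero probability under the model")
            betas[0, : offsets[x[0] + 1] - offsets[x[0]]] = 1.0
        total_ll += ll
        i0_first = offsets[x[0]]
        m_first = offsets[x[0] + 1] - i0_first
        prior_counts[i0_first:i0_first + m_first] += (
            alphas[0, :m_first] * betas[0, :m_first]
        )
        if N < 2:
            continue
        # beta(n+1) / c(n+1), aligned with transition step n
        wbetas = betas[1:] / scales[1:, None]
        al = alphas[:-1]
        for g, ((xi, k, xj), steps) in enumerate(groups):
            mi = offsets[xi + 1] - offsets[xi]
            mj = offsets[xj + 1] - offsets[xj]
            outer = al[steps, :mi].T @ wbetas[steps, :mj]
            counts[offsets[xi]:offsets[xi] + mi, k,
                   offsets[xj]:offsets[xj] + mj] += blocks[g, :mi, :mj] * outer
    return counts, prior_counts, total_ll


def em_fit(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
) -> tuple[CSCGModel, list[float]]:
    """Baum-Welch on one or more sequences (treated as independent draws).

    Returns the fitted model and the per-iteration penalized log-likelihood
    trace (the optimized likelihood — joint, or conditional on actions,
    depending on ``cfg.normalization`` — plus the Dirichlet-MAP smoothing
    penalty), which is non-decreasing.  The returned model always stores the
    joint tensor P(z', a | z).  With ``n_restarts > 1``, restart r >= 1
    re-initializes randomly with seed ``cfg.seed + r`` and the best final
    penalized value wins.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    if not seqs:
        raise ValueError("at least one sequence is required")
    for seq in seqs:
        seq.validate_against(model.n_obs, model.n_actions)
        if seq.actions is None and model.n_actions > 1:
            raise ValueError("sequences lack actions but the model has n_actions > 1")
    offsets = model.allocation.offsets
    mmax = int(model.allocation.clones_per_obs.max())
    groups_per_seq = [_bigram_groups(seq) for seq in seqs]
    best: tuple[CSCGModel, list[float]] | None = None
    for r in range(cfg.n_restarts):
        m0 = model if r == 0 else create_model(
            model.allocation, model.n_actions, seed=cfg.seed + r, init="random"
        )
        work_dtype = np.dtype(cfg.dtype)
        if cfg.normalization == "conditional":
            T = _conditionalize(m0.transitions).astype(work_dtype)
        else:
            T = m0.transitions.astype(work_dtype)
        pi = m0.prior.astype(work_dtype)
        trace: list[float] = []
        counts = None
        for _ in range(cfg.max_iters):
            counts, prior_counts, ll = _raw_estep(
                T, pi, offsets, mmax, seqs, groups_per_seq
            )
            trace.append(ll + _penalty(T, pi, cfg.pseudocount))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= cfg.tol * abs(trace[-2]):
                break
            T = _normalize_counts(counts, cfg.pseudocount, cfg.normalization)
            pi = prior_counts + cfg.pseudocount
            pi /= pi.sum()
        else:
            warnings.warn(
                f"EM stopped at max_iters={cfg.max_iters} without reaching tol",
                stacklevel=2,
            )
        T_joint = _joint_from_counts(
            counts.astype(np.float64), cfg.pseudocount, m0.transitions
        )
        pi_out = pi.astype(np.float64)
        pi_out /= pi_out.sum()
        fitted = CSCGModel(
            model.allocation, model.n_actions, pi_out, T_joint,
            metadata={
                "seed": cfg.seed, "pseudocount": cfg.pseudocount,
                "normalization": cfg.normalization,
                "loglik_trace": [float(v) for v in trace],
            },
        )
        if best is None or trace[-1] > best[1][-1]:
            best = (fitted, trace)
    return best


def viterbi_train(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
) -> CSCGModel:
    """Hard-EM refinement: decode MAP paths, count, renormalize, repeat.

    Uses no pseudocount, so the refined transition matrix has support only on
    decoded transitions; states never visited by any decoded path keep their
    previous rows and become prunable (see :func:`used_states`).  Decoding and
    re-estimation run under ``cfg.normalization`` (action-conditioned by
    default, matching :func:`em_fit`); the returned model stores the joint
    tensor.  Iteration stops when the decoded paths are stable or after
    ``cfg.max_iters`` rounds.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    for seq in seqs:
        seq.validate_against(model.n_obs, model.n_actions)
    offsets = model.allocation.offsets
    H = model.n_states
    if cfg.normalization == "conditional":
        T = _conditionalize(model.transitions)
    else:
        T = model.transitions.copy()
    pi = model.prior.copy()
    counts = None
    prev_paths = None
    for _ in range(cfg.max_iters):
        paths = []
        for seq in seqs:
            x = seq.observations
            a = seq.effective_actions()
            path = np.zeros(x.size, dtype=np.int64)
            logp = _kernels.viterbi(T, pi, offsets, x, a, path)
            if not np.isfinite(logp):
                raise ValueError("sequence has no positive-probability clone path")
            paths.append(path)
        if prev_paths is not None and all(
            np.array_equal(p, q) for p, q in zip(paths, prev_paths)
        ):
            break
        prev_paths = paths
        counts = np.zeros((H, model.n_actions, H))
        prior_counts = np.zeros(H)
        for seq, path in zip(seqs, paths):
            a = seq.effective_actions()
            np.add.at(counts, (path[:-1], a, path[1:]), 1.0)
            prior_counts[path[0]] += 1.0
        T = _normalize_counts(counts, 0.0, cfg.normalization)
        # dead states keep their previous rows so they stay merely unused
        rs = counts.reshape(H, -1).sum(axis=1)
        if cfg.normalization == "conditional":
            dead_rows = counts.sum(axis=2) <= 0
            prevT = _conditionalize(model.transitions)
            T[dead_rows] = prevT[dead_rows]
        else:
            T[rs <= 0] = model.transitions[rs <= 0]
        ps = prior_counts.sum()
        pi = prior_counts / ps if ps > 0 else pi
    if counts is None:  # paths stable immediately; rebuild joint from a decode count
        counts = np.zeros((H, model.n_actions, H))
        prior_counts = np.zeros(H)
        for seq, path in zip(seqs, prev_paths):
            a = seq.effective_actions()
            np.add.at(counts, (path[:-1], a, path[1:]), 1.0)
            prior_counts[path[0]] += 1.0
    T_joint = _joint_from_counts(counts, 0.0, model.transitions)
    out = CSCGModel(
        model.allocation, model.n_actions, pi, T_joint, metadata=dict(model.metadata)
    )
    out.metadata["pseudocount"] = 0.0
    return out


def fit_two_phase(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
) -> tuple[CSCGModel, list[float]]:
    """Two-phase schedule: smoothed EM, then zero-pseudocount Viterbi refinement.

    This is the standard training recipe for map learning: the pseudocount aids
    EM convergence, and the hard refinement removes the smoothing mass and the
    redundant clones it keeps alive.
    """
    m, trace = em_fit(model, seqs, cfg)
    m = viterbi_train(m, seqs, cfg)
    return m, trace


def memorize(
    allocation: CloneAllocation,
    n_actions: int,
    seqs: list[ActionObservationSequence],
    pseudocount: float = 1e-6,
) -> CSCGModel:
    """Rapid sequence memorization: a dynamic-Markov-coding pass over the data.

    Walks each sequence once, assigning the next observation to an existing
    clone when the (current clone, action, next symbol) context has been seen
    before and to a fresh clone of that symbol otherwise (wrapping around when
    a symbol's clones are exhausted).  The transition counts of the resulting
    clone paths, lightly smoothed, form a model that already encodes the
    temporal contexts verbatim.

    Strictly repeating structure (laps, prototypical routes) makes the
    symmetric first-order solution a strong attractor for randomly initialized
    EM; memorization followed by EM refinement — which merges the redundant
    clones this pass over-allocates — reaches the higher-order solution
    instead.  Use as a warm start for :func:`em_fit` / :func:`viterbi_train`.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    offsets = allocation.offsets
    H = allocation.n_states
    counts = np.zeros((H, n_actions, H))
    prior_counts = np.zeros(H)
    next_free = np.zeros(allocation.n_obs, dtype=np.int64)
    context: dict[tuple[int, int, int], int] = {}

    def fresh(symbol: int) -> int:
        M = allocation.clones_per_obs[symbol]
        z = int(offsets[symbol] + next_free[symbol] % M)
        next_free[symbol] += 1
        return z

    start_of: dict[int, int] = {}
    for seq in seqs:
        seq.validate_against(allocation.n_obs, n_actions)
        x = seq.observations
        a = seq.effective_actions()
        if int(x[0]) not in start_of:
            start_of[int(x[0])] = fresh(int(x[0]))
        z = start_of[int(x[0])]
        prior_counts[z] += 1.0
        for n in range(x.size - 1):
            key = (z, int(a[n]), int(x[n + 1]))
            if key not in context:
                context[key] = fresh(int(x[n + 1]))
            z_next = context[key]
            counts[z, a[n], z_next] += 1.0
            z = z_next
    T = _joint_from_counts(counts, pseudocount, np.full((H, n_actions, H), 1.0 / (n_actions * H)))
    prior = prior_counts + pseudocount
    prior /= prior.sum()
    return CSCGModel(allocation, n_actions, prior, T)


def split_refine(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
    rounds: int = 10,
    min_context_count: int = 3,
    action_set_count: int = 20,
    verbose: bool = False,
) -> CSCGModel:
    """Context-driven clone splitting for deterministic-under-action worlds.

    EM merges clones readily but has no move that un-merges them: once two
    locations share a clone, the merged state is a stable fixed point even
    when a split would raise the objective.  This pass supplies the missing
    splitting move of dynamic Markov coding.  In each round the MAP decode of
    the training data is grouped, for every clone, by incoming context
    (previous clone, previous action); contexts whose observed
    action-successor behavior conflicts cannot be the same latent location, so
    they are separated onto free clones of the same symbol.  The reassigned
    paths are hard-counted, re-estimated, and stabilized with Viterbi
    training; the loop stops when no clone splits or no free clones remain.

    Appropriate when each (location, action) has a unique outcome (gridworlds
    with observed actions); on genuinely stochastic worlds it would oversplit
    and should not be used.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    m = model.copy()
    offsets = m.allocation.offsets
    symbol_of = m.allocation.symbol_of_state()
    H = m.n_states
    for _ in range(rounds):
        paths = [_decode_path(m, seq, cfg.normalization) for seq in seqs]
        # merge move: clones of one symbol with identical successor behavior
        # are duplicates of the same latent location; folding them returns
        # their clones to the free pool so later splits are never starved
        folded = _fold_duplicate_clones(
            paths, [s.effective_actions() for s in seqs], symbol_of,
            min_count=action_set_count,
        )
        if folded and verbose:
            print(f"split_refine: folded {len(folded)} duplicate clones")
        used = np.unique(np.concatenate(paths))
        free_by_symbol: dict[int, list[int]] = {}
        for j in range(m.n_obs):
            free_by_symbol[j] = [
                z for z in range(offsets[j], offsets[j + 1]) if z not in set(used)
            ]
        # incoming context -> successor evidence, per clone
        ctx_succ: dict[int, dict] = {}
        for seq, path in zip(seqs, paths):
            a = seq.effective_actions()
            for n in range(1, len(path) - 1):
                z = int(path[n])
                ctx = (int(path[n - 1]), int(a[n - 1]))
                nxt = (int(a[n]), int(path[n + 1]))
                ctx_succ.setdefault(z, {}).setdefault(ctx, Counter())[nxt] += 1
        reassign: dict[tuple[int, tuple[int, int]], int] = {}
        n_splits = 0
        for z, ctxs in ctx_succ.items():
            if len(ctxs) < 2:
                continue
            # majority successor per action, per context; well-sampled
            # contexts also commit to their full observed action set — two
            # locations with complementary legal moves (e.g. opposite
            # corners) never conflict on a shared action, and only the
            # action-availability signature separates them
            sigs = {}
            actsets = {}
            for ctx, counter in ctxs.items():
                best: dict[int, tuple[int, int]] = {}
                total = sum(counter.values())
                if total < min_context_count:
                    continue
                for (act, nz), c in counter.items():
                    if act not in best or c > best[act][1]:
                        best[act] = (nz, c)
                sigs[ctx] = {act: nz for act, (nz, _) in best.items()}
                actsets[ctx] = (
                    frozenset(sigs[ctx]) if total >= action_set_count else None
                )
            if len(sigs) < 2:
                continue
            # greedy clustering: contexts join the first cluster they do not
            # conflict with (a conflict = different successor for one action,
            # or different committed action sets)
            clusters: list[tuple[dict, list, list]] = []
            for ctx in sorted(sigs, key=lambda c: -sum(ctxs[c].values())):
                sig = sigs[ctx]
                aset = actsets[ctx]
                for proto, proto_aset, members in clusters:
                    if not all(proto.get(a_, nz) == nz for a_, nz in sig.items()):
                        continue
                    if aset is not None and proto_aset[0] is not None \
                            and aset != proto_aset[0]:
                        continue
                    proto.update(sig)
                    if proto_aset[0] is None:
                        proto_aset[0] = aset
                    members.append(ctx)
                    break
                else:
                    clusters.append((dict(sig), [aset], [ctx]))
            if len(clusters) < 2:
                continue
            free = free_by_symbol[int(symbol_of[z])]
            for proto, _aset, members in clusters[1:]:
                if not free:
                    break
                nz = free.pop(0)
                n_splits += 1
                for ctx in members:
                    reassign[(z, ctx)] = nz
        if verbose:
            free_left = sum(len(v) for v in free_by_symbol.values())
            print(f"split_refine: {n_splits} splits, {free_left} free clones left")
        if n_splits == 0 and not folded:
            break
        counts = np.zeros((H, m.n_actions, H))
        prior_counts = np.zeros(H)
        for seq, path in zip(seqs, paths):
            a = seq.effective_actions()
            new_path = path.copy()
            for n in range(1, len(path) - 1):
                key = (int(path[n]), (int(path[n - 1]), int(a[n - 1])))
                if key in reassign:
                    new_path[n] = reassign[key]
            np.add.at(counts, (new_path[:-1], a, new_path[1:]), 1.0)
            prior_counts[new_path[0]] += 1.0
        T = _normalize_counts(counts, cfg.pseudocount, cfg.normalization)
        dead = counts.sum(axis=2) <= 0 if cfg.normalization == "conditional" else None
        if cfg.normalization == "conditional":
            prevT = _conditionalize(m.transitions)
            T[dead] = prevT[dead]
        else:
            rs = counts.reshape(H, -1).sum(axis=1)
            T[rs <= 0] = m.transitions[rs <= 0]
        pi = prior_counts + cfg.pseudocount
        pi /= pi.sum()
        m = CSCGModel(
            m.allocation, m.n_actions, pi,
            _joint_from_counts(counts, cfg.pseudocount, m.transitions),
        )
        m = viterbi_train(m, seqs, cfg)
    return m


def split_merge_refine(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
    cycles: int = 4,
    consolidation_iters: int = 100,
) -> CSCGModel:
    """Alternate context-splitting and EM consolidation until stable.

    Each cycle runs :func:`split_refine` (which also folds duplicate clones),
    then a short warm-started soft-EM pass to redistribute probability mass,
    then Viterbi training.  On deterministic-under-action worlds this
    recovers maps that cold EM alone leaves with self-consistent cross-location
    merges — the split and merge moves are the two halves of dynamic Markov
    coding that plain Baum-Welch lacks.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    m = model
    for _ in range(cycles):
        before = m.transitions
        m = split_refine(m, seqs, cfg)
        cons_cfg = EMConfig(
            max_iters=consolidation_iters, pseudocount=cfg.pseudocount,
            tol=1e-11, seed=cfg.seed, normalization=cfg.normalization,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            soft, _ = em_fit(m.smoothed(1e-6), seqs, cons_cfg)
        m = viterbi_train(soft, seqs, cfg)
        if np.array_equal(m.transitions, before):
            break
    return m


def _fold_duplicate_clones(paths, actions_per_seq, symbol_of, min_count: int):
    """Rewrite decoded paths in place, merging same-symbol duplicate clones.

    Two well-sampled clones are duplicates when their majority successor maps
    (action -> next clone) and observed action sets coincide exactly.  Returns
    the mapping of folded clone -> surviving clone.
    """
    sig: dict[int, dict] = {}
    totals: Counter = Counter()
    for path, a in zip(paths, actions_per_seq):
        for n in range(len(path) - 1):
            z = int(path[n])
            sig.setdefault(z, {}).setdefault(int(a[n]), Counter())[
                int(path[n + 1])
            ] += 1
            totals[z] += 1
    canon: dict[tuple, int] = {}
    fold: dict[int, int] = {}
    for z, per_action in sig.items():
        if totals[z] < min_count:
            continue
        key = (
            int(symbol_of[z]),
            tuple(sorted(
                (a_, cnt.most_common(1)[0][0]) for a_, cnt in per_action.items()
            )),
        )
        if key in canon and canon[key] != z:
            fold[z] = canon[key]
        else:
            canon[key] = z
    # resolve chains (a -> b -> c)
    for z in list(fold):
        while fold[z] in fold:
            fold[z] = fold[fold[z]]
    if fold:
        for path in paths:
            for n in range(len(path)):
                z = int(path[n])
                if z in fold:
                    path[n] = fold[z]
    return fold


def _decode_path(model: CSCGModel, seq: ActionObservationSequence, normalization: str):
    """MAP clone path under the model's conditional or joint tensor."""
    x = seq.observations
    a = seq.effective_actions()
    T = (
        _conditionalize(model.transitions)
        if normalization == "conditional"
        else model.transitions
    )
    path = np.zeros(x.size, dtype=np.int64)
    logp = _kernels.viterbi(T, model.prior, model.allocation.offsets, x, a, path)
    if not np.isfinite(logp):
        raise ValueError("sequence has no positive-probability clone path")
    return path


def used_states(model: CSCGModel, seqs) -> np.ndarray:
    """Sorted unique states appearing in the Viterbi decode of ``seqs``."""
    from .infer import viterbi_decode

    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    return np.unique(np.concatenate([viterbi_decode(model, s).states for s in seqs]))


def prune_model(model: CSCGModel, keep: np.ndarray) -> tuple[CSCGModel, np.ndarray]:
    """Drop states not in ``keep``, re-indexing clones per symbol.

    Every symbol retains at least one clone (its first, if none were kept) so
    the allocation stays valid.  Returns the pruned model and the array of old
    state ids in new-index order.  Rows are renormalized over the kept columns;
    for a zero-pseudocount refined model the removed columns carry no mass, so
    decoded-path likelihoods are unchanged.
    """
    keep = np.unique(np.asarray(keep, dtype=np.int64))
    symbol_of = model.allocation.symbol_of_state()
    kept_mask = np.zeros(model.n_states, dtype=bool)
    kept_mask[keep] = True
    offsets = model.allocation.offsets
    for j in range(model.n_obs):
        if not kept_mask[offsets[j]:offsets[j + 1]].any():
            kept_mask[offsets[j]] = True
    old_ids = np.flatnonzero(kept_mask)
    new_clones = np.bincount(symbol_of[old_ids], minlength=model.n_obs)
    allocation = CloneAllocation(new_clones)
    T = model.transitions[np.ix_(old_ids, np.arange(model.n_actions), old_ids)]
    rs = T.reshape(len(old_ids), -1).sum(axis=1)
    rs[rs <= 0] = 1.0
    T = T / rs[:, None, None]
    prior = model.prior[old_ids]
    prior = prior / prior.sum() if prior.sum() > 0 else np.full(len(old_ids), 1 / len(old_ids))
    emission = model.emission[old_ids] if model.emission is not None else None
    pruned = CSCGModel(allocation, model.n_actions, prior, T, emission, dict(model.metadata))
    return pruned, old_ids


# ---------------------------------------------------------------------------
# Dense-emission EM (schema transfer)
# ---------------------------------------------------------------------------

def _dense_forward_backward(T_a, pi, emission, x, a):
    """Scaled forward/backward over all H states with a dense emission."""
    N = x.size
    H = pi.size
    alphas = np.zeros((N, H))
    betas = np.zeros((N, H))
    scales = np.zeros(N)
    al = pi * emission[:, x[0]]
    s = al.sum()
    if s <= 0:
        return None, None, None, -np.inf
    alphas[0] = al / s
    scales[0] = s
    loglik = np.log(s)
    for n in range(N - 1):
        al = (alphas[n] @ T_a[a[n]]) * emission[:, x[n + 1]]
        s = al.sum()
        if s <= 0:
            return None, None, None, -np.inf
        alphas[n + 1] = al / s
        scales[n + 1] = s
        loglik += np.log(s)
    betas[N - 1] = 1.0
    for n in range(N - 2, -1, -1):
        betas[n] = (T_a[a[n]] @ (emission[:, x[n + 1]] * betas[n + 1])) / scales[n + 1]
    return alphas, betas, scales, float(loglik)


def learn_emission(
    model: CSCGModel,
    seqs: list[ActionObservationSequence],
    cfg: EMConfig,
) -> tuple[CSCGModel, list[float]]:
    """EM over the dense emission matrix only; transitions stay bit-identical.

    This is schema transfer: the transition tensor learned in a familiar
    environment is frozen and reused, and only the state-to-observation mapping
    is relearned (initialized uniform) from walks in the new environment.
    """
    if isinstance(seqs, ActionObservationSequence):
        seqs = [seqs]
    H, E = model.n_states, model.n_obs
    emission = (
        model.emission.copy()
        if model.emission is not None
        else np.full((H, E), 1.0 / E)
    )
    T_a = np.ascontiguousarray(model.transitions.transpose(1, 0, 2))  # (Na, H, H)
    trace: list[float] = []
    for _ in range(cfg.max_iters):
        obs_counts = np.zeros((H, E))
        total_ll = 0.0
        for seq in seqs:
            seq.validate_against(E, model.n_actions)
            x = seq.observations
            a = seq.effective_actions()
            alphas, betas, _, ll = _dense_forward_backward(T_a, model.prior, emission, x, a)
            if not np.isfinite(ll):
                raise ValueError("sequence has zero probability under the frozen schema")
            total_ll += ll
            gammas = alphas * betas  # each row sums to 1 under the scaling used
            np.add.at(obs_counts.T, x, gammas)
        trace.append(total_ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= cfg.tol * abs(trace[-2]):
            break
        smoothed = obs_counts + cfg.pseudocount
        rs = smoothed.sum(axis=1)
        dead = rs <= 0
        smoothed[dead] = 1.0
        rs[dead] = E
        emission = smoothed / rs[:, None]
    out = CSCGModel(
        model.allocation, model.n_actions, model.prior, model.transitions,
        emission, dict(model.metadata),
    )
    return out, trace


# ---------------------------------------------------------------------------
# Online / adaptive EM
# ---------------------------------------------------------------------------

@dataclass
class OnlineEMState:
    """Exponentially forgotten expected-count statistics A^(b)."""

    stats: np.ndarray      # (H, n_actions, H)
    memory: float          # lambda in (0, 1)
    batch_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.memory < 1.0:
            raise ValueError("memory parameter lambda must lie strictly in (0, 1)")

    @classmethod
    def initial(cls, model: CSCGModel, memory: float) -> "OnlineEMState":
        H = model.n_states
        return cls(np.zeros((H, model.n_actions, H)), memory)


def online_em_update(
    state: OnlineEMState,
    model: CSCGModel,
    batch: ActionObservationSequence,
) -> tuple[OnlineEMState, CSCGModel]:
    """One adaptive EM step on a batch of the stream.

    ``A^(b) = lambda * A^(b-1) + (1 - lambda) * sum_n xi(n)`` with expectations
    taken under the previous batch's model, then ``T^(b)`` by row normalization
    of ``A^(b)``.  The prior is left untouched: for long streams the initial
    state contributes negligibly.  Smaller lambda forgets old environments
    faster, letting the model track a changing world.
    """
    if len(batch) < 2:
        raise ValueError("batch must contain at least one transition")
    # row normalization leaves unseen transitions at exactly zero; evaluate
    # the expectations under a minimally smoothed copy so a novel transition
    # in the incoming batch does not have probability zero
    eval_model = model.smoothed(1e-12) if np.any(model.transitions == 0) else model
    s = e_step(eval_model, batch)
    new_stats = state.memory * state.stats + (1.0 - state.memory) * s.counts
    H = model.n_states
    T = new_stats.copy()
    rs = T.reshape(H, -1).sum(axis=1)
    dead = rs <= 0
    T[dead] = model.transitions[dead]
    rs[dead] = 1.0
    T /= rs[:, None, None]
    new_model = CSCGModel(
        model.allocation, model.n_actions, model.prior.copy(), T,
        None if model.emission is None else model.emission.copy(),
        dict(model.metadata),
    )
    return OnlineEMState(new_stats, state.memory, state.batch_index + 1), new_model


def forward_op_count(model: CSCGModel, seq: ActionObservationSequence) -> int:
    """Multiply-accumulate operations of one forward pass.

    Grows with the per-symbol clone counts, not the alphabet size: the block
    structure is what makes large alphabets free.
    """
    x, _, offsets = _prep(model, seq)
    return int(_kernels.count_flops_forward(offsets, x))
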