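"""Inference on trained CSCGs.

Because the action and the next hidden state are collapsed into one variable,
the model is a chain and belief propagation on it is exact: a single forward
sweep gives filtered (online) posteriors, adding the backward sweep gives
smoothed posteriors, and max-product gives the MAP clone path.  Uncertain
sensation enters as soft evidence — a per-step likelihood vector over symbols —
of which a hard observation is the one-hot special case.  When actions are
unavailable they are integrated out analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import ActionObservationSequence, CSCGModel

__all__ = [
    "SoftEvidence",
    "CloneActivationTrace",
    "DecodePath",
    "NoPathError",
    "filter",
    "smooth",
    "viterbi_decode",
    "correct_errors",
    "sample",
    "replay_observation_sample",
    "predict_next_observation",
    "next_symbol_accuracy",
    "environment_posterior",
    "environment_clone_sets",
]


class NoPathError(ValueError):
    """No positive-probability clone path exists for the sequence."""


@dataclass
class SoftEvidence:
    """Per-step likelihood vectors over observation symbols.

    ``observations`` has shape (N, E); entries are non-negative likelihoods and
    need not normalize.  ``actions`` (length N-1) may be None, in which case
    actions are marginalized during inference.
    """

    observations: np.ndarray
    actions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.float64)
        if self.observations.ndim != 2:
            raise ValueError("soft evidence must be an (N, E) array")
        if np.any(self.observations < 0):
            raise ValueError("evidence likelihoods must be non-negative")
        if not np.all(self.observations.sum(axis=1) > 0):
            raise ValueError("each evidence step needs at least one positive entry")
        if self.actions is not None:
            self.actions = np.asarray(self.actions, dtype=np.int64)
            if self.actions.shape != (self.observations.shape[0] - 1,):
                raise ValueError("actions must have length N - 1")

    @classmethod
    def from_hard(cls, seq: ActionObservationSequence, n_obs: int) -> "SoftEvidence":
        like = np.zeros((len(seq), n_obs))
        like[np.arange(len(seq)), seq.observations] = 1.0
        return cls(like, None if seq.actions is None else seq.actions.copy())

    @classmethod
    def softened(
        cls, seq: ActionObservationSequence, n_obs: int, epsilon: float
    ) -> "SoftEvidence":
        """(1-eps) on the observed symbol, eps spread uniformly over all symbols."""
        like = np.full((len(seq), n_obs), epsilon / n_obs)
        like[np.arange(len(seq)), seq.observations] += 1.0 - epsilon
        return cls(like, None if seq.actions is None else seq.actions.copy())


@dataclass
class CloneActivationTrace:
    """Per-step posterior over all H clones; each row sums to 1."""

    activations: np.ndarray   # (N, H)
    mode: str                 # "filtered" | "smoothed"

    def __len__(self) -> int:
        return self.activations.shape[0]

    def active_sets(self, threshold: float = 0.01) -> list[np.ndarray]:
        """Clones whose posterior exceeds ``threshold`` at each step."""
        return [np.flatnonzero(row > threshold) for row in self.activations]

    def to_tsv(self, path, threshold: float = 0.0) -> None:
        with open(path, "w") as fh:
            fh.write("step\tclone_id\tactivation\n")
            for n, row in enumerate(self.activations):
                for z in np.flatnonzero(row > threshold):
                    fh.write(f"{n}\t{z}\t{row[z]:.12g}\n")


@dataclass
class DecodePath:
    """MAP clone path and its log-probability."""

    states: np.ndarray
    logprob: float


def _as_soft(model: CSCGModel, evidence) -> SoftEvidence:
    if isinstance(evidence, ActionObservationSequence):
        evidence.validate_against(model.n_obs, model.n_actions)
        return SoftEvidence.from_hard(evidence, model.n_obs)
    if isinstance(evidence, SoftEvidence):
        if evidence.observations.shape[1] != model.n_obs:
            raise ValueError("evidence alphabet does not match the model")
        if evidence.actions is not None and evidence.actions.size:
            if evidence.actions.max() >= model.n_actions or evidence.actions.min() < 0:
                raise ValueError("action id out of range")
        return evidence
    raise TypeError(f"unsupported evidence type {type(evidence).__name__}")


def _state_evidence(model: CSCGModel, obs_like: np.ndarray) -> np.ndarray:
    """Lift symbol likelihoods to state likelihoods through the emission."""
    if model.emission is not None:
        return obs_like @ model.emission.T
    return obs_like[:, model.allocation.symbol_of_state()]


def _forward_soft(model: CSCGModel, ev: SoftEvidence):
    sev = _state_evidence(model, ev.observations)
    N = sev.shape[0]
    T_marg = model.action_marginal()
    alphas = np.zeros_like(sev)
    scales = np.zeros(N)
    al = model.prior * sev[0]
    s = al.sum()
    if s <= 0:
        raise ValueError("zero-probability evidence at step 0")
    alphas[0] = al / s
    scales[0] = s
    for n in range(N - 1):
        if ev.actions is not None:
            trans = model.transitions[:, ev.actions[n], :]
        else:
            trans = T_marg
        al = (alphas[n] @ trans) * sev[n + 1]
        s = al.sum()
        if s <= 0:
            raise ValueError(f"zero-probability evidence at step {n + 1}")
        alphas[n + 1] = al / s
        scales[n + 1] = s
    return alphas, scales, sev


def filter(model: CSCGModel, evidence) -> CloneActivationTrace:
    """Exact filtered (online) clone posteriors under hard or soft evidence."""
    ev = _as_soft(model, evidence)
    alphas, _, _ = _forward_soft(model, ev)
    return CloneActivationTrace(alphas, "filtered")


def smooth(model: CSCGModel, evidence) -> CloneActivationTrace:
    """Exact smoothed clone posteriors (forward and backward sweeps)."""
    ev = _as_soft(model, evidence)
    alphas, scales, sev = _forward_soft(model, ev)
    N = sev.shape[0]
    T_marg = model.action_marginal()
    betas = np.zeros_like(alphas)
    betas[N - 1] = 1.0
    for n in range(N - 2, -1, -1):
        if ev.actions is not None:
            trans = model.transitions[:, ev.actions[n], :]
        else:
            trans = T_marg
        betas[n] = (trans @ (sev[n + 1] * betas[n + 1])) / scales[n + 1]
    post = alphas * betas
    post /= post.sum(axis=1, keepdims=True)
    return CloneActivationTrace(post, "smoothed")


def viterbi_decode(model: CSCGModel, seq: ActionObservationSequence) -> DecodePath:
    """MAP clone path under hard evidence; ties go to the lowest state index."""
    seq.validate_against(model.n_obs, model.n_actions)
    if seq.actions is None and model.n_actions > 1:
        raise ValueError("Viterbi decoding of a multi-action model requires actions")
    x = seq.observations
    a = seq.effective_actions()
    path = np.zeros(x.size, dtype=np.int64)
    logp = _kernels.viterbi(
        model.transitions, model.prior, model.allocation.offsets, x, a, path
    )
    if not np.isfinite(logp):
        raise NoPathError("sequence has no positive-probability clone path")
    return DecodePath(path, float(logp))


def symbol_posterior(trace: CloneActivationTrace, model: CSCGModel) -> np.ndarray:
    """Collapse a clone trace to an (N, E) posterior over symbols."""
    if model.emission is not None:
        return trace.activations @ model.emission
    post = np.zeros((len(trace), model.n_obs))
    offsets = model.allocation.offsets
    for j in range(model.n_obs):
        post[:, j] = trace.activations[:, offsets[j]:offsets[j + 1]].sum(axis=1)
    return post


def correct_errors(
    model: CSCGModel,
    noisy_seq: ActionObservationSequence,
    noise_rate: float,
) -> tuple[ActionObservationSequence, np.ndarray]:
    """Online MAP correction of a corrupted observation stream.

    The channel is modeled as emitting a uniformly random wrong symbol with
    probability ``noise_rate``, which makes the per-step evidence vector
    ``1 - noise_rate`` on the observed symbol and ``noise_rate / (E-1)``
    elsewhere.  A single forward pass then yields the filtered posterior over
    the *true* symbol at each step; the output takes its argmax.  Returns the
    corrected sequence and the (N, E) per-step symbol posterior.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must lie in [0, 1)")
    E = model.n_obs
    like = np.full((len(noisy_seq), E), noise_rate / max(E - 1, 1))
    like[np.arange(len(noisy_seq)), noisy_seq.observations] = 1.0 - noise_rate
    ev = SoftEvidence(like, None if noisy_seq.actions is None else noisy_seq.actions)
    trace = filter(model, ev)
    post = symbol_posterior(trace, model)
    corrected = np.argmax(post, axis=1)
    return ActionObservationSequence(corrected, noisy_seq.actions), post


def sample(
    model: CSCGModel,
    n_steps: int,
    start=None,
    seed: int = 0,
) -> tuple[ActionObservationSequence, np.ndarray]:
    """Ancestral sampling (replay): draw a clone path with its actions/symbols.

    ``start`` may be a clone id, a distribution over clones, or None (the
    model prior).  Each step jointly draws ``(a_n, z_{n+1}) ~ T(z_n, ., .)``;
    the observation is the clone's symbol (or a draw from the dense emission).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    H = model.n_states
    if start is None:
        z = int(rng.choice(H, p=model.prior))
    elif np.isscalar(start) or isinstance(start, (int, np.integer)):
        z = int(start)
        if not 0 <= z < H:
            raise ValueError(f"start clone {z} out of range [0, {H})")
    else:
        p = np.asarray(start, dtype=np.float64)
        if p.shape != (H,) or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("start distribution must be a non-negative length-H vector")
        z = int(rng.choice(H, p=p / p.sum()))
    symbol_of = model.allocation.symbol_of_state()

    def emit(state: int) -> int:
        if model.emission is not None:
            return int(rng.choice(model.n_obs, p=model.emission[state]))
        return int(symbol_of[state])

    states = np.zeros(n_steps, dtype=np.int64)
    obs = np.zeros(n_steps, dtype=np.int64)
    acts = np.zeros(max(n_steps - 1, 0), dtype=np.int64)
    states[0], obs[0] = z, emit(z)
    flat = model.transitions.reshape(H, -1)
    for n in range(n_steps - 1):
        row = flat[z]
        idx = int(rng.choice(row.size, p=row / row.sum()))
        acts[n] = idx // H
        z = idx % H
        states[n + 1], obs[n + 1] = z, emit(z)
    actions = acts if n_steps > 1 else None
    return ActionObservationSequence(obs, actions), states


def predict_next_observation(
    model: CSCGModel, seq: ActionObservationSequence
) -> np.ndarray:
    """One-step-ahead predictive distributions P(x_{n+1} | x_{1:n}, a_{1:n}).

    Returns an (N-1, E) array; row n conditions on the first n+1 observations
    and the action taken at step n.
    """
    trace = filter(model, seq)
    a = seq.effective_actions()
    N = len(seq)
    preds = np.zeros((N - 1, model.n_obs))
    for n in range(N - 1):
        nxt = trace.activations[n] @ model.transitions[:, a[n], :]
        if model.emission is not None:
            preds[n] = nxt @ model.emission
        else:
            offsets = model.allocation.offsets
            preds[n] = np.add.reduceat(nxt, offsets[:-1])
    return preds


def next_symbol_accuracy(
    model: CSCGModel, seq: ActionObservationSequence, burn_in: int = 10
) -> float:
    """Fraction of post-burn-in steps whose argmax prediction is correct."""
    preds = predict_next_observation(model, seq)
    hits = np.argmax(preds, axis=1) == seq.observations[1:]
    return float(hits[burn_in:].mean())


def replay_observation_sample(
    model: CSCGModel, prefix: ActionObservationSequence, seed: int = 0
) -> int:
    """Sample the next observation from the forward-predicted distribution.

    This is the replay mechanism: during forward message passing the messages
    from hidden states to the observation are normalized and sampled, so
    replayed continuations stay consistent with the context of the prefix.
    """
    trace = filter(model, prefix)
    nxt = trace.activations[-1] @ model.action_marginal()
    if model.emission is not None:
        dist = nxt @ model.emission
    else:
        dist = np.add.reduceat(nxt, model.allocation.offsets[:-1])
    dist = dist / dist.sum()
    rng = np.random.default_rng(seed)
    return int(rng.choice(model.n_obs, p=dist))


def environment_posterior(
    model: CSCGModel,
    env_clone_sets: list[np.ndarray],
    seq,
) -> np.ndarray:
    """Per-step probability of being in each environment.

    ``env_clone_sets`` partitions (a subset of) the states into one set per
    environment; the posterior of environment e at step n is the filtered
    posterior mass on its states, renormalized across environments.
    """
    seen: set[int] = set()
    for s in env_clone_sets:
        ss = set(int(v) for v in np.asarray(s).ravel())
        if seen & ss:
            raise ValueError("environment clone sets must be disjoint")
        seen |= ss
    trace = filter(model, seq)
    post = np.stack(
        [trace.activations[:, np.asarray(s, dtype=np.int64)].sum(axis=1)
         for s in env_clone_sets],
        axis=1,
    )
    totals = post.sum(axis=1, keepdims=True)
    totals[totals <= 0] = 1.0
    return post / totals


def environment_clone_sets(
    model: CSCGModel, walks: list[ActionObservationSequence]
) -> list[np.ndarray]:
    """Assign each state to the environment whose walks use it the most.

    Sums the forward messages of each environment's walk to get a per-
    environment distribution over hidden states, then partitions the states by
    argmax.  States never activated by any walk are left out.
    """
    scores = np.zeros((len(walks), model.n_states))
    for e, walk in enumerate(walks):
        scores[e] = filter(model, walk).activations.sum(axis=0)
    total = scores.sum(axis=0)
    owner = np.argmax(scores, axis=0)
    return [
        np.flatnonzero((owner == e) & (total > 1e-9)) for e in range(len(walks))
    ]
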