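"""Core data types for clone-structured cognitive graphs (CSCGs).

A CSCG is a hidden Markov model in which every hidden state emits exactly one
observation symbol ("clones" of that symbol) and transitions jointly emit the
agent's action: ``T[i, k, j] = P(z' = j, a = k | z = i)``.  Clones of the same
symbol are indistinguishable bottom-up but specialize to different temporal
contexts during learning, which is what lets the model disambiguate aliased
observations.

States are indexed symbol-major: all clones of symbol 0 first, then symbol 1,
and so on, so the clones of symbol ``j`` occupy a contiguous index range.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CloneAllocation",
    "ActionObservationSequence",
    "CSCGModel",
    "create_model",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class CloneAllocation:
    """Maps each observation symbol to a contiguous block of hidden states.

    Parameters
    ----------
    clones_per_obs
        Number of clones allocated to each observation symbol (all >= 1).
    """

    clones_per_obs: np.ndarray

    def __init__(self, clones_per_obs) -> None:
        arr = np.asarray(clones_per_obs, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("clones_per_obs must be a non-empty 1-D array")
        if np.any(arr < 1):
            raise ValueError("every symbol needs at least one clone")
        object.__setattr__(self, "clones_per_obs", arr)

    @classmethod
    def uniform(cls, n_obs: int, n_clones: int) -> "CloneAllocation":
        """Allocate the same number of clones to every symbol."""
        if n_obs < 1 or n_clones < 1:
            raise ValueError("n_obs and n_clones must be positive")
        return cls(np.full(n_obs, n_clones, dtype=np.int64))

    @property
    def n_obs(self) -> int:
        return int(self.clones_per_obs.size)

    @property
    def n_states(self) -> int:
        return int(self.clones_per_obs.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative start index of each symbol's clone block, length E+1."""
        return np.concatenate(([0], np.cumsum(self.clones_per_obs)))

    def clone_range(self, symbol: int) -> range:
        """Half-open index range of the clones of ``symbol``."""
        if not 0 <= symbol < self.n_obs:
            raise ValueError(f"symbol {symbol} out of range [0, {self.n_obs})")
        off = self.offsets
        return range(int(off[symbol]), int(off[symbol + 1]))

    def symbol_of_state(self) -> np.ndarray:
        """Vector of length H giving the emitted symbol of each state."""
        return np.repeat(np.arange(self.n_obs), self.clones_per_obs)


def clone_range(allocation: CloneAllocation, symbol: int) -> range:
    """Module-level alias for :meth:`CloneAllocation.clone_range`."""
    return allocation.clone_range(symbol)


@dataclass
class ActionObservationSequence:
    """A stream of sensation-action pairs (x_1, a_1), ..., (x_{N-1}, a_{N-1}), x_N.

    ``actions`` may be ``None`` for action-free cloned-HMM use; otherwise it has
    one fewer entry than ``observations``.
    """

    observations: np.ndarray
    actions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=np.int64)
        if self.observations.ndim != 1 or self.observations.size == 0:
            raise ValueError("observations must be a non-empty 1-D array")
        if np.any(self.observations < 0):
            raise ValueError("observation ids must be non-negative")
        if self.actions is not None:
            self.actions = np.asarray(self.actions, dtype=np.int64)
            if self.actions.shape != (self.observations.size - 1,):
                raise ValueError(
                    "actions must have length len(observations) - 1, got "
                    f"{self.actions.shape[0]} for N={self.observations.size}"
                )
            if np.any(self.actions < 0):
                raise ValueError("action ids must be non-negative")

    def __len__(self) -> int:
        return int(self.observations.size)

    def validate_against(self, n_obs: int, n_actions: int) -> None:
        if self.observations.max() >= n_obs:
            raise ValueError("observation id out of the declared alphabet")
        if self.actions is not None and self.actions.size and self.actions.max() >= n_actions:
            raise ValueError("action id out of the declared alphabet")

    def effective_actions(self) -> np.ndarray:
        """Actions as an array; an all-zero stream when actions are absent."""
        if self.actions is None:
            return np.zeros(max(len(self) - 1, 0), dtype=np.int64)
        return self.actions

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\taction\tobservation\n")
            acts = self.effective_actions() if self.actions is not None else None
            for n, x in enumerate(self.observations):
                if acts is not None and n < len(self) - 1:
                    fh.write(f"{n}\t{acts[n]}\t{x}\n")
                else:
                    fh.write(f"{n}\t\t{x}\n")

    @classmethod
    def from_tsv(cls, path) -> "ActionObservationSequence":
        obs: list[int] = []
        acts: list[int] = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["step", "action", "observation"]:
                raise ValueError(f"unexpected TSV header: {header!r}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"malformed TSV row: {line!r}")
                _, a, x = parts
                obs.append(int(x))
                if a != "":
                    acts.append(int(a))
        actions = np.asarray(acts, dtype=np.int64) if acts else None
        if actions is not None and actions.size != len(obs) - 1:
            raise ValueError("action column must be empty exactly on the last row")
        return cls(np.asarray(obs, dtype=np.int64), actions)


@dataclass
class CSCGModel:
    """Prior plus action-conditional clone transition tensor.

    Attributes
    ----------
    allocation
        Clone block structure shared by all operations.
    prior
        Initial state distribution pi over all H states.
    transitions
        Tensor of shape (H, n_actions, H) with ``T[i, k, j] = P(z'=j, a=k | z=i)``;
        every state's (action, next-state) block sums to one.
    emission
        Only in dense mode: row-stochastic matrix P(x | z) of shape (H, E), used
        for schema transfer where the transition structure is frozen and only the
        observation mapping is relearned.  In clone-structured mode the emission
        is the implicit 0/1 block structure and is never materialized.
    metadata
        Free-form dict (seed, training config, log-likelihood trace) carried
        through save/load.
    """

    allocation: CloneAllocation
    n_actions: int
    prior: np.ndarray
    transitions: np.ndarray
    emission: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def emission_mode(self) -> str:
        return "dense" if self.emission is not None else "clone-structured"

    @property
    def n_states(self) -> int:
        return self.allocation.n_states

    @property
    def n_obs(self) -> int:
        return self.allocation.n_obs

    def validate(self, atol: float = 1e-9) -> None:
        H = self.n_states
        if self.prior.shape != (H,):
            raise ValueError("prior has wrong shape")
        if self.transitions.shape != (H, self.n_actions, H):
            raise ValueError("transition tensor has wrong shape")
        if np.any(self.prior < 0) or np.any(self.transitions < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.prior.sum() - 1.0) > atol:
            raise ValueError("prior does not sum to 1")
        rows = self.transitions.reshape(H, -1).sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > atol:
            raise ValueError("transition rows do not sum to 1")
        if self.emission is not None:
            if self.emission.shape != (H, self.n_obs):
                raise ValueError("emission matrix has wrong shape")
            if np.max(np.abs(self.emission.sum(axis=1) - 1.0)) > atol:
                raise ValueError("emission rows do not sum to 1")

    def action_marginal(self) -> np.ndarray:
        """Transition matrix of the cloned HMM obtained by integrating out actions."""
        return self.transitions.sum(axis=1)

    def smoothed(self, kappa: float) -> "CSCGModel":
        """Return a copy with pseudocount ``kappa`` mixed into every transition.

        Re-smoothing a refined (zero-pseudocount) model is how soft, partially
        overlapping clone activations are produced at inference time.
        """
        H = self.n_states
        T = self.transitions + kappa
        T /= T.reshape(H, -1).sum(axis=1)[:, None, None]
        prior = self.prior + kappa
        prior /= prior.sum()
        return CSCGModel(
            self.allocation, self.n_actions, prior, T,
            None if self.emission is None else self.emission.copy(),
            dict(self.metadata),
        )

    def with_dwell(self, rho: float) -> "CSCGModel":
        """Mix a self-transition (dwell) probability ``rho`` into every state.

        ``T'[i, k, j] = (1 - rho) T[i, k, j] + rho/n_actions * [i == j]``.
        Augmenting a trained model this way at inference time models temporal
        stretching — the agent lingering in a physically elongated segment —
        without retraining, and without making arbitrary state jumps as cheap
        as staying put (which uniform smoothing does).
        """
        if not 0.0 <= rho < 1.0:
            raise ValueError("dwell probability must lie in [0, 1)")
        H = self.n_states
        T = (1.0 - rho) * self.transitions.copy()
        idx = np.arange(H)
        T[idx, :, idx] += rho / self.n_actions
        return CSCGModel(
            self.allocation, self.n_actions, self.prior.copy(), T,
            None if self.emission is None else self.emission.copy(),
            dict(self.metadata),
        )

    def copy(self) -> "CSCGModel":
        return CSCGModel(
            self.allocation, self.n_actions, self.prior.copy(),
            self.transitions.copy(),
            None if self.emission is None else self.emission.copy(),
            dict(self.metadata),
        )


def create_model(
    allocation: CloneAllocation,
    n_actions: int,
    seed: int = 0,
    init: str = "random",
) -> CSCGModel:
    """Build a valid CSCG with uniform prior and uniform or random transitions.

    ``random`` draws i.i.d. strictly-positive entries on (0, 1] per transition
    cell and normalizes jointly over (action, next state); the same seed gives a
    bitwise-identical model.
    """
    if n_actions < 1:
        raise ValueError("n_actions must be >= 1")
    H = allocation.n_states
    prior = np.full(H, 1.0 / H)
    if init == "uniform":
        T = np.full((H, n_actions, H), 1.0 / (n_actions * H))
    elif init == "random":
        rng = np.random.default_rng(seed)
        T = 1.0 - rng.random((H, n_actions, H))  # entries in (0, 1]
        T /= T.reshape(H, -1).sum(axis=1)[:, None, None]
    else:
        raise ValueError(f"unknown init {init!r}")
    model = CSCGModel(allocation, int(n_actions), prior, T, metadata={"seed": int(seed)})
    model.validate()
    return model


def save_model(model: CSCGModel, path) -> None:
    """Write a model archive: named numeric arrays plus a JSON metadata block."""
    meta = {
        "version": _FORMAT_VERSION,
        "n_obs": model.n_obs,
        "n_actions": model.n_actions,
        **{k: v for k, v in model.metadata.items()},
    }
    buf = io.BytesIO()
    arrays = {
        "clones_per_obs": model.allocation.clones_per_obs,
        "prior": model.prior.astype(np.float64),
        "transitions": model.transitions.astype(np.float64),
    }
    if model.emission is not None:
        arrays["emission"] = model.emission.astype(np.float64)
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("meta.json", json.dumps(meta))


def load_model(path) -> CSCGModel:
    """Load a model archive written by :func:`save_model` (exact round trip)."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "meta.json" not in names:
                raise ValueError("model archive is missing meta.json")
            meta = json.loads(zf.read("meta.json"))
        with np.load(path) as data:
            clones = data["clones_per_obs"]
            prior = data["prior"]
            transitions = data["transitions"]
            emission = data["emission"] if "emission" in data.files else None
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted model archive: {exc}") from exc
    if meta.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model-archive version {meta.get('version')!r}")
    allocation = CloneAllocation(clones)
    metadata = {k: v for k, v in meta.items() if k not in ("version", "n_obs", "n_actions")}
    model = CSCGModel(
        allocation, int(meta["n_actions"]), prior, transitions, emission, metadata
    )
    model.validate(atol=1e-6)
    return model
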