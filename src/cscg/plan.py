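"""Planning as inference on a learned CSCG.

A goal — an observation symbol or a specific clone — is reached by sweeping
forward through the model to find the earliest horizon at which the goal has
positive support, then extracting the action sequence with a max-product
backward pass.  On the deterministic support graph this specializes to
breadth-first search over (state, action) edges, which is how it is
implemented; the returned plan is the minimal-horizon feasible one.

Smoothing gives every transition nonzero probability, which would make every
goal trivially "feasible"; planning therefore runs on the support graph of the
un-smoothed transitions, obtained by stripping edges at pseudocount scale (see
:func:`planning_support`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .model import CSCGModel

__all__ = [
    "Plan",
    "InfeasibleGoalError",
    "ExecutionResult",
    "observation_goal",
    "clone_goal",
    "planning_support",
    "plan",
    "execute_and_replan",
]


class InfeasibleGoalError(ValueError):
    """Goal has no positive support within the searched horizon."""

    def __init__(self, message: str, horizon_searched: int):
        super().__init__(message)
        self.horizon_searched = horizon_searched


@dataclass
class Plan:
    """An executable action sequence with its expected sensory consequences."""

    actions: np.ndarray
    expected_observations: np.ndarray
    clone_path: np.ndarray
    horizon: int


@dataclass
class ExecutionResult:
    reached: bool
    trajectory: list
    actions_taken: list
    replans: int
    failure_reason: str = ""


def observation_goal(symbol: int):
    return ("obs", int(symbol))


def clone_goal(state: int):
    return ("clone", int(state))


def planning_support(
    model: CSCGModel,
    threshold_scale: float = 10.0,
    blocked_states=None,
    removed_edges=None,
) -> np.ndarray:
    """Boolean (H, n_actions, H) mask of transitions considered really present.

    An entry survives if it exceeds ``threshold_scale`` times the smallest
    entry of its row — pseudocount-only edges sit at the row minimum, real
    edges carry observed counts far above it.  For zero-pseudocount (refined)
    models the row minimum is 0 and all positive entries survive.  A uniform
    (never-updated) row has no entries above its own minimum and yields no
    edges.  ``blocked_states`` removes all edges into and out of the given
    states; ``removed_edges`` is an iterable of (state, action) pairs to drop.
    """
    H = model.n_states
    T = model.transitions
    row_min = T.reshape(H, -1).min(axis=1)
    support = T > (threshold_scale * row_min)[:, None, None]
    if blocked_states is not None:
        blocked = np.asarray(list(blocked_states), dtype=np.int64)
        support[blocked, :, :] = False
        support[:, :, blocked] = False
    if removed_edges is not None:
        for i, k in removed_edges:
            support[i, k, :] = False
    return support


def _goal_states(model: CSCGModel, goal) -> np.ndarray:
    if isinstance(goal, tuple) and len(goal) == 2 and goal[0] in ("obs", "clone"):
        kind, value = goal
    elif np.isscalar(goal) or isinstance(goal, (int, np.integer)):
        kind, value = "clone", int(goal)
    else:
        raise TypeError("goal must be observation_goal(j), clone_goal(z) or a clone id")
    if kind == "clone":
        if not 0 <= value < model.n_states:
            raise ValueError(f"goal clone {value} out of range")
        return np.array([value], dtype=np.int64)
    rng_ = model.allocation.clone_range(value)
    return np.arange(rng_.start, rng_.stop, dtype=np.int64)


def _start_states(model: CSCGModel, start) -> np.ndarray:
    if np.isscalar(start) or isinstance(start, (int, np.integer)):
        z = int(start)
        if not 0 <= z < model.n_states:
            raise ValueError(f"start clone {z} out of range")
        return np.array([z], dtype=np.int64)
    belief = np.asarray(start, dtype=np.float64)
    if belief.shape != (model.n_states,) or np.any(belief < 0) or belief.sum() <= 0:
        raise ValueError("start belief must be a non-negative length-H vector")
    return np.flatnonzero(belief > 0)


def plan(
    model: CSCGModel,
    start,
    goal,
    max_horizon: int = 1000,
    threshold_scale: float = 10.0,
    blocked_states=None,
    removed_edges=None,
    support: np.ndarray | None = None,
) -> Plan:
    """Minimal-horizon feasible plan from ``start`` to ``goal``.

    ``start`` is a clone id or a belief vector (all positive-mass states are
    admissible starting points); ``goal`` is :func:`observation_goal`,
    :func:`clone_goal` or a bare clone id.  The forward sweep stops at the
    first horizon where some goal state is reachable; backward extraction
    follows stored predecessors, with ties broken toward the lowest action id.
    Raises :class:`InfeasibleGoalError` if no goal state has support within
    ``max_horizon`` steps.
    """
    if max_horizon < 0:
        raise ValueError("max_horizon must be >= 0")
    if support is None:
        support = planning_support(model, threshold_scale, blocked_states, removed_edges)
    H = model.n_states
    goal_set = np.zeros(H, dtype=bool)
    goal_set[_goal_states(model, goal)] = True
    sources = _start_states(model, start)
    symbol_of = model.allocation.symbol_of_state()

    dist = np.full(H, -1, dtype=np.int64)
    parent_state = np.full(H, -1, dtype=np.int64)
    parent_action = np.full(H, -1, dtype=np.int64)
    queue: deque[int] = deque()
    for z in sources:
        dist[z] = 0
        queue.append(int(z))
    hit = next((int(z) for z in sources if goal_set[z]), None)
    while queue and hit is None:
        i = queue.popleft()
        d = dist[i]
        if d >= max_horizon:
            continue
        succ = support[i]  # (n_actions, H)
        for k in range(model.n_actions):
            for j in np.flatnonzero(succ[k]):
                if dist[j] == -1:
                    dist[j] = d + 1
                    parent_state[j] = i
                    parent_action[j] = k
                    if goal_set[j]:
                        hit = int(j)
                        break
                    queue.append(int(j))
            if hit is not None:
                break
    if hit is None:
        raise InfeasibleGoalError(
            f"goal unreachable within horizon {max_horizon}", max_horizon
        )
    path = [hit]
    acts: list[int] = []
    while parent_state[path[-1]] != -1:
        acts.append(int(parent_action[path[-1]]))
        path.append(int(parent_state[path[-1]]))
    path.reverse()
    acts.reverse()
    clone_path = np.asarray(path, dtype=np.int64)
    return Plan(
        actions=np.asarray(acts, dtype=np.int64),
        expected_observations=symbol_of[clone_path],
        clone_path=clone_path,
        horizon=len(acts),
    )


def _goal_satisfied(model: CSCGModel, goal, clone: int, observation: int) -> bool:
    if isinstance(goal, tuple) and goal[0] == "obs":
        return observation == goal[1]
    goal_clone = goal[1] if isinstance(goal, tuple) else int(goal)
    return clone == goal_clone


def execute_and_replan(
    env,
    model: CSCGModel,
    initial_plan: Plan,
    goal,
    start_pos,
    max_steps: int = 1000,
    threshold_scale: float = 10.0,
) -> ExecutionResult:
    """Closed-loop execution: follow the plan, replan around rejected actions.

    Actions are executed in ``env`` from ``start_pos``.  When the environment
    rejects an action (a wall the model did not know about), the failed
    (clone, action) edge is removed from the planning graph, the agent
    re-localizes by exact filtering of its action-observation history from the
    plan's start clone, and a fresh plan is computed.  Terminates on goal,
    on an infeasible replan, or when the step budget runs out.
    """
    pos = (int(start_pos[0]), int(start_pos[1]))
    belief = np.zeros(model.n_states)
    belief[initial_plan.clone_path[0]] = 1.0
    removed: set[tuple[int, int]] = set()
    current = initial_plan
    step_in_plan = 0
    trajectory = [pos]
    actions_taken: list[int] = []
    replans = 0
    obs = env.observation(pos)
    symbol_of = model.allocation.symbol_of_state()
    for _ in range(max_steps):
        clone = int(np.argmax(belief))
        if _goal_satisfied(model, goal, clone, obs):
            return ExecutionResult(True, trajectory, actions_taken, replans)
        if step_in_plan >= len(current.actions):
            return ExecutionResult(
                False, trajectory, actions_taken, replans, "plan exhausted before goal"
            )
        action = int(current.actions[step_in_plan])
        nxt = env.step(pos, action)
        if nxt is None:
            removed.add((clone, action))
            replans += 1
            try:
                current = plan(
                    model, clone, goal,
                    max_horizon=max_steps,
                    threshold_scale=threshold_scale,
                    removed_edges=removed,
                )
            except InfeasibleGoalError:
                return ExecutionResult(
                    False, trajectory, actions_taken, replans, "goal unreachable after pruning"
                )
            step_in_plan = 0
            continue
        pos = nxt
        obs = env.observation(pos)
        trajectory.append(pos)
        actions_taken.append(action)
        # exact filtering update restricted to the clones of the new observation
        belief = belief @ model.transitions[:, action, :]
        mask = symbol_of == obs
        belief = belief * mask
        total = belief.sum()
        if total <= 0:
            return ExecutionResult(
                False, trajectory, actions_taken, replans, "lost localization"
            )
        belief /= total
        step_in_plan += 1
    return ExecutionResult(False, trajectory, actions_taken, replans, "step budget exhausted")
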