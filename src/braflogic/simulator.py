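"""Continuous-time Markov chain simulation of logical networks.

Dynamics follow the asynchronous-update stochastic semantics popularized by
MaBoSS: in a given model state, every non-input node whose current level
differs from its logical target level contributes one enabled transition
(one level up at rate ``k_up`` or one level down at rate ``k_down``).  The
next event is drawn with the Gillespie direct method: waiting time
exponential in the total propensity, transition chosen proportionally to its
rate.  An ensemble of independent trajectories is aggregated into a mean
stochastic trajectory (per-node expected normalized level over a time grid)
and a distribution over model states at ``t_end``.

Two implementations are provided: a readable pure-Python sampler for single
trajectories (:func:`simulate_trajectory`) and a compiled ensemble kernel
(:func:`simulate`) in which every node's rule is pre-evaluated into a
target-level lookup table over its regulators.  For small models,
:func:`exact_transient_distribution` integrates the master equation exactly
and serves as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import expm_multiply

from .logic_core import (
    ModelValidationError,
    NetworkModel,
    UnknownNodeError,
    target_level,
)

__all__ = [
    "InitialCondition",
    "SimulationConfig",
    "Transition",
    "Trajectory",
    "SimulationResult",
    "enabled_transitions",
    "draw_next_event",
    "simulate_trajectory",
    "simulate",
    "exact_transient_distribution",
    "phenotype_score",
]


# ---------------------------------------------------------------------------
# Initial conditions and configuration
# ---------------------------------------------------------------------------


class InitialCondition:
    """Per-node activation probabilities.

    A node starts at its ``max_level`` with probability ``a`` and at 0 with
    probability ``1 - a``, independently across nodes and trajectories.
    Unspecified nodes default to ``a = 0.5``.  Probabilities 0 and 1 are
    treated as deterministic (no randomness is consumed for those nodes).
    """

    def __init__(self, activations: dict[str, float] | None = None):
        self._act: dict[str, float] = {}
        for node, a in (activations or {}).items():
            a = float(a)
            if not (0.0 <= a <= 1.0):
                raise ModelValidationError(
                    f"initial activation for {node} outside [0,1]: {a}"
                )
            self._act[node] = a

    def activation(self, node: str) -> float:
        return self._act.get(node, 0.5)

    def items(self):
        return self._act.items()

    def updated(self, overrides: dict[str, float]) -> "InitialCondition":
        merged = dict(self._act)
        merged.update(overrides)
        return InitialCondition(merged)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, InitialCondition) and self._act == other._act

    def __repr__(self) -> str:
        return f"InitialCondition({self._act!r})"


def resolve_initial_condition(
    model: NetworkModel, ic: "InitialCondition | str | dict | None"
) -> InitialCondition:
    """Accept an :class:`InitialCondition`, a profile name, or a plain dict."""
    if ic is None:
        return InitialCondition()
    if isinstance(ic, InitialCondition):
        return ic
    if isinstance(ic, str):
        if ic not in model.initial_profiles:
            raise ModelValidationError(
                f"unknown initial-condition profile: {ic!r} "
                f"(available: {sorted(model.initial_profiles)})"
            )
        return InitialCondition(model.initial_profiles[ic])
    return InitialCondition(dict(ic))


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble size, horizon and output grid for a simulation."""

    n_trajectories: int = 5000
    t_end: float = 50.0
    n_time_points: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ModelValidationError("n_trajectories must be >= 1")
        if not self.t_end > 0:
            raise ModelValidationError("t_end must be > 0")
        if self.n_time_points < 2:
            raise ModelValidationError("n_time_points must be >= 2")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Transition:
    """A single admissible one-level move of one node."""

    node: str
    direction: int  # +1 or -1
    rate: float


# ---------------------------------------------------------------------------
# Elementary operations (pure Python)
# ---------------------------------------------------------------------------


def enabled_transitions(model: NetworkModel, state: dict[str, int]) -> list[Transition]:
    """Transitions admissible in ``state``: one per node off its target level."""
    out: list[Transition] = []
    for spec in model.nodes:
        if spec.is_input or spec.name in model.forced:
            continue
        current = state[spec.name]
        target = target_level(model, spec.name, state)
        if current < target:
            out.append(Transition(spec.name, +1, spec.rate_up))
        elif current > target:
            out.append(Transition(spec.name, -1, spec.rate_down))
    return out


def draw_next_event(
    transitions: list[Transition], rng: np.random.Generator
) -> tuple[Transition, float]:
    """Gillespie direct method: exponential waiting time, rate-proportional choice."""
    if not transitions:
        raise ValueError("no enabled transitions: state is absorbing")
    rates = np.array([t.rate for t in transitions])
    total = rates.sum()
    wait = rng.exponential(1.0 / total)
    idx = int(rng.choice(len(transitions), p=rates / total))
    return transitions[idx], wait


@dataclass
class Trajectory:
    """A single piecewise-constant sample path."""

    initial_state: dict[str, int]
    events: list[tuple[float, str, int]]  # (time, node, new level)
    final_state: dict[str, int]
    t_end: float

    def state_at(self, t: float) -> dict[str, int]:
        state = dict(self.initial_state)
        for time, node, level in self.events:
            if time > t:
                break
            state[node] = level
        return state


def draw_initial_state(
    model: NetworkModel, ic: InitialCondition, rng: np.random.Generator
) -> dict[str, int]:
    state: dict[str, int] = {}
    for spec in model.nodes:
        if spec.name in model.forced:
            state[spec.name] = model.forced[spec.name]
        elif spec.name in model.init_overrides:
            state[spec.name] = model.init_overrides[spec.name]
        else:
            a = ic.activation(spec.name)
            if a <= 0.0:
                state[spec.name] = 0
            elif a >= 1.0:
                state[spec.name] = spec.max_level
            else:
                state[spec.name] = spec.max_level if rng.random() < a else 0
    return state


def simulate_trajectory(
    model: NetworkModel,
    ic: InitialCondition | str | None,
    t_end: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Sample one stochastic trajectory up to ``t_end`` (or absorption)."""
    ic = resolve_initial_condition(model, ic)
    initial = draw_initial_state(model, ic, rng)
    state = dict(initial)
    events: list[tuple[float, str, int]] = []
    t = 0.0
    while True:
        transitions = enabled_transitions(model, state)
        if not transitions:
            break
        transition, wait = draw_next_event(transitions, rng)
        t += wait
        if t >= t_end:
            break
        state[transition.node] += transition.direction
        events.append((t, transition.node, state[transition.node]))
    return Trajectory(
        initial_state=initial,
        events=events,
        final_state=dict(state),
        t_end=t_end,
    )


# ---------------------------------------------------------------------------
# Compiled ensemble simulation
# ---------------------------------------------------------------------------

_TABLE_CAP = 2**20


@dataclass
class CompiledModel:
    """Array encoding of a model for the ensemble kernel.

    Each movable node's rule is flattened into a target-level lookup table
    indexed by the mixed-radix encoding of its regulators' levels.
    """

    node_names: list[str]
    max_level: np.ndarray  # int8[n]
    can_move: np.ndarray  # bool[n]
    rate_up: np.ndarray  # float64[n]
    rate_down: np.ndarray  # float64[n]
    reg_ptr: np.ndarray  # int32[n + 1]
    reg_idx: np.ndarray  # int32[nnz]
    tbl_ptr: np.ndarray  # int64[n + 1]
    tbl: np.ndarray  # int8[total table size]
    dep_ptr: np.ndarray  # int32[n + 1]
    dep_idx: np.ndarray  # int32[nnz]


def compile_model(model: NetworkModel) -> CompiledModel:
    model.check_structure()
    names = model.node_names
    n = len(names)
    max_level = np.array([s.max_level for s in model.nodes], dtype=np.int8)
    rate_up = np.array([s.rate_up for s in model.nodes], dtype=np.float64)
    rate_down = np.array([s.rate_down for s in model.nodes], dtype=np.float64)
    can_move = np.array(
        [not s.is_input and s.name not in model.forced for s in model.nodes],
        dtype=np.bool_,
    )

    reg_lists: list[list[int]] = [[] for _ in range(n)]
    tables: list[np.ndarray] = [np.empty(0, dtype=np.int8) for _ in range(n)]
    for i, spec in enumerate(model.nodes):
        if not can_move[i]:
            continue
        exprs = model.rules[spec.name]
        regs = sorted({model.node_index(node) for e in exprs for node, _ in e.literals()})
        sizes = [int(max_level[r]) + 1 for r in regs]
        total = int(np.prod(sizes)) if regs else 1
        if total > _TABLE_CAP:
            raise ModelValidationError(
                f"rule for {spec.name} depends on too many regulator states ({total})"
            )
        table = np.zeros(total, dtype=np.int8)
        reg_names = [names[r] for r in regs]
        for flat, combo in enumerate(itertools.product(*[range(s) for s in sizes])):
            assignment = dict(zip(reg_names, combo))
            level = 0
            for l in range(spec.max_level, 0, -1):
                if exprs[l - 1].evaluate(assignment):
                    level = l
                    break
            table[flat] = level
        reg_lists[i] = regs
        tables[i] = table

    dep_sets: list[set[int]] = [{i} for i in range(n)]
    for i in range(n):
        for r in reg_lists[i]:
            dep_sets[r].add(i)

    reg_ptr = np.zeros(n + 1, dtype=np.int32)
    tbl_ptr = np.zeros(n + 1, dtype=np.int64)
    dep_ptr = np.zeros(n + 1, dtype=np.int32)
    for i in range(n):
        reg_ptr[i + 1] = reg_ptr[i] + len(reg_lists[i])
        tbl_ptr[i + 1] = tbl_ptr[i] + len(tables[i])
        dep_ptr[i + 1] = dep_ptr[i] + len(dep_sets[i])
    reg_idx = np.array(
        [r for regs in reg_lists for r in regs], dtype=np.int32
    ) if reg_ptr[-1] else np.empty(0, dtype=np.int32)
    tbl = np.concatenate(tables) if tbl_ptr[-1] else np.empty(0, dtype=np.int8)
    dep_idx = np.array(
        [d for deps in dep_sets for d in sorted(deps)], dtype=np.int32
    )

    return CompiledModel(
        node_names=names,
        max_level=max_level,
        can_move=can_move,
        rate_up=rate_up,
        rate_down=rate_down,
        reg_ptr=reg_ptr,
        reg_idx=reg_idx,
        tbl_ptr=tbl_ptr,
        tbl=tbl,
        dep_ptr=dep_ptr,
        dep_idx=dep_idx,
    )


@njit(cache=True)
def _node_target(k, state, max_level, reg_ptr, reg_idx, tbl_ptr, tbl):
    idx = 0
    for j in range(reg_ptr[k], reg_ptr[k + 1]):
        r = reg_idx[j]
        idx = idx * (max_level[r] + 1) + state[r]
    return tbl[tbl_ptr[k] + idx]


@njit(cache=True)
def _ensemble_kernel(
    n_traj,
    t_end,
    times,
    max_level,
    can_move,
    rate_up,
    rate_down,
    reg_ptr,
    reg_idx,
    tbl_ptr,
    tbl,
    dep_ptr,
    dep_idx,
    init_a,
    init_level,
    seed,
):
    np.random.seed(seed)
    n_nodes = max_level.shape[0]
    n_pts = times.shape[0]
    acc = np.zeros((n_pts, n_nodes), dtype=np.float64)
    finals = np.zeros((n_traj, n_nodes), dtype=np.int8)
    state = np.zeros(n_nodes, dtype=np.int8)
    target = np.zeros(n_nodes, dtype=np.int8)
    prop = np.zeros(n_nodes, dtype=np.float64)

    for tr in range(n_traj):
        # --- initial state -------------------------------------------------
        for k in range(n_nodes):
            if init_level[k] >= 0:
                state[k] = init_level[k]
            else:
                a = init_a[k]
                if a <= 0.0:
                    state[k] = 0
                elif a >= 1.0:
                    state[k] = max_level[k]
                else:
                    if np.random.random() < a:
                        state[k] = max_level[k]
                    else:
                        state[k] = 0
        total = 0.0
        for k in range(n_nodes):
            if can_move[k]:
                target[k] = _node_target(
                    k, state, max_level, reg_ptr, reg_idx, tbl_ptr, tbl
                )
                if state[k] < target[k]:
                    prop[k] = rate_up[k]
                elif state[k] > target[k]:
                    prop[k] = rate_down[k]
                else:
                    prop[k] = 0.0
            else:
                target[k] = state[k]
                prop[k] = 0.0
            total += prop[k]

        t = 0.0
        g = 0
        n_events = 0
        while True:
            if total <= 1e-12:
                t_next = t_end + 1.0
            else:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                t_next = t - np.log(u) / total
            # record the held state on grid points inside [t, t_next)
            while g < n_pts and times[g] < t_next:
                for k in range(n_nodes):
                    acc[g, k] += state[k]
                g += 1
            if t_next >= t_end:
                for k in range(n_nodes):
                    finals[tr, k] = state[k]
                break
            # --- choose and apply the transition ---------------------------
            r = np.random.random() * total
            cum = 0.0
            chosen = -1
            for k in range(n_nodes):
                p = prop[k]
                if p > 0.0:
                    cum += p
                    chosen = k
                    if r < cum:
                        break
            if state[chosen] < target[chosen]:
                state[chosen] += 1
            else:
                state[chosen] -= 1
            t = t_next
            n_events += 1
            # --- incremental propensity update -----------------------------
            for j in range(dep_ptr[chosen], dep_ptr[chosen + 1]):
                d = dep_idx[j]
                if not can_move[d]:
                    continue
                old = prop[d]
                target[d] = _node_target(
                    d, state, max_level, reg_ptr, reg_idx, tbl_ptr, tbl
                )
                if state[d] < target[d]:
                    prop[d] = rate_up[d]
                elif state[d] > target[d]:
                    prop[d] = rate_down[d]
                else:
                    prop[d] = 0.0
                total += prop[d] - old
            if n_events % 4096 == 0:
                total = 0.0
                for k in range(n_nodes):
                    total += prop[k]
    return acc, finals


@dataclass
class SimulationResult:
    """Ensemble summary: mean trajectory, final states, phenotype scores."""

    times: np.ndarray
    mean_activation: pd.DataFrame  # time grid x node, E[level] / max_level
    final_states: np.ndarray  # (n_trajectories, n_nodes) int8
    node_names: list[str]
    max_level: np.ndarray
    phenotypes: dict[str, str]
    config: SimulationConfig
    _distribution: dict[tuple[int, ...], float] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_trajectories(self) -> int:
        return self.final_states.shape[0]

    def node_column(self, node: str) -> int:
        try:
            return self.node_names.index(node)
        except ValueError:
            raise UnknownNodeError(f"unknown node: {node}") from None

    def final_mean_level(self, node: str) -> float:
        return float(self.final_states[:, self.node_column(node)].mean())

    def final_activation(self, node: str) -> float:
        """Expected normalized level of ``node`` in the t_end distribution."""
        k = self.node_column(node)
        return float(self.final_states[:, k].mean() / self.max_level[k])

    def state_distribution(self) -> dict[tuple[int, ...], float]:
        """Empirical distribution over full model states at ``t_end``."""
        if self._distribution is None:
            uniq, counts = np.unique(self.final_states, axis=0, return_counts=True)
            n = self.final_states.shape[0]
            self._distribution = {
                tuple(int(v) for v in row): c / n for row, c in zip(uniq, counts)
            }
        return self._distribution

    def phenotype_scores(self) -> dict[str, float]:
        return {name: phenotype_score(self, name) for name in self.phenotypes}

    def to_timecourse_frame(self) -> pd.DataFrame:
        return self.mean_activation.copy()


def simulate(
    model: NetworkModel,
    ic: InitialCondition | str | dict | None,
    config: SimulationConfig,
) -> SimulationResult:
    """Simulate an ensemble of stochastic trajectories of ``model``.

    Deterministic given ``config.seed``: the same (model, initial condition,
    config) triple yields a bit-identical result.
    """
    ic = resolve_initial_condition(model, ic)
    compiled = compile_model(model)
    n = len(compiled.node_names)

    init_a = np.empty(n, dtype=np.float64)
    init_level = np.full(n, -1, dtype=np.int8)
    for k, name in enumerate(compiled.node_names):
        if name in model.forced:
            init_level[k] = model.forced[name]
        elif name in model.init_overrides:
            init_level[k] = model.init_overrides[name]
        init_a[k] = ic.activation(name)

    times = np.linspace(0.0, config.t_end, config.n_time_points)
    kernel_seed = np.uint32(np.random.SeedSequence(config.seed).generate_state(1)[0])
    acc, finals = _ensemble_kernel(
        config.n_trajectories,
        float(config.t_end),
        times,
        compiled.max_level,
        compiled.can_move,
        compiled.rate_up,
        compiled.rate_down,
        compiled.reg_ptr,
        compiled.reg_idx,
        compiled.tbl_ptr,
        compiled.tbl,
        compiled.dep_ptr,
        compiled.dep_idx,
        init_a,
        init_level,
        kernel_seed,
    )
    norm = config.n_trajectories * compiled.max_level.astype(np.float64)
    mean = pd.DataFrame(acc / norm, index=times, columns=compiled.node_names)
    mean.index.name = "time"
    return SimulationResult(
        times=times,
        mean_activation=mean,
        final_states=finals,
        node_names=compiled.node_names,
        max_level=compiled.max_level,
        phenotypes=dict(model.phenotypes),
        config=config,
    )


def phenotype_score(result: SimulationResult, phenotype: str) -> float:
    """Expected normalized level of the phenotype's read-out node at ``t_end``."""
    if phenotype not in result.phenotypes:
        raise UnknownNodeError(f"unknown phenotype: {phenotype}")
    return result.final_activation(result.phenotypes[phenotype])


# ---------------------------------------------------------------------------
# Exact transient distribution (master-equation oracle)
# ---------------------------------------------------------------------------

_STATE_SPACE_CAP = 2**14


def exact_transient_distribution(
    model: NetworkModel,
    ic: InitialCondition | str | dict | None,
    t: float,
) -> dict[tuple[int, ...], float]:
    """Solve the master equation exactly for a small model.

    Builds the CTMC generator Q over the full state space (one admissible
    one-level move per off-target node, rows summing to zero) and computes
    ``pi(t) = exp(Q^T t) pi(0)`` with a sparse matrix-exponential action.
    Returns the distribution over full states as tuples in node order.
    """
    ic = resolve_initial_condition(model, ic)
    model.check_structure()
    names = model.node_names
    sizes = [s.max_level + 1 for s in model.nodes]
    n_states = int(np.prod(sizes))
    if n_states > _STATE_SPACE_CAP:
        raise ModelValidationError(
            f"state space too large for exact solution: {n_states} states"
        )

    strides = np.ones(len(sizes), dtype=np.int64)
    for i in range(len(sizes) - 2, -1, -1):
        strides[i] = strides[i + 1] * sizes[i + 1]

    def encode(levels: tuple[int, ...]) -> int:
        return int(sum(l * s for l, s in zip(levels, strides)))

    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    for combo in itertools.product(*[range(s) for s in sizes]):
        s_idx = encode(combo)
        state = dict(zip(names, combo))
        for transition in enabled_transitions(model, state):
            k = model.node_index(transition.node)
            new = list(combo)
            new[k] += transition.direction
            rows.append(encode(tuple(new)))
            cols.append(s_idx)
            vals.append(transition.rate)
            diag[s_idx] -= transition.rate
    rows.extend(range(n_states))
    cols.extend(range(n_states))
    vals.extend(diag)
    A = coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()

    # initial distribution: independent product over nodes
    pi0 = np.ones(1)
    for spec in model.nodes:
        if spec.name in model.forced:
            level = model.forced[spec.name]
            p = np.zeros(spec.max_level + 1)
            p[level] = 1.0
        elif spec.name in model.init_overrides:
            p = np.zeros(spec.max_level + 1)
            p[model.init_overrides[spec.name]] = 1.0
        else:
            a = ic.activation(spec.name)
            p = np.zeros(spec.max_level + 1)
            p[0] = 1.0 - a
            p[spec.max_level] += a
        pi0 = np.kron(pi0, p)

    pi_t = expm_multiply(A * t, pi0)
    pi_t = np.clip(pi_t, 0.0, None)
    pi_t /= pi_t.sum()

    out: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(*[range(s) for s in sizes]):
        p = float(pi_t[encode(combo)])
        if p > 0.0:
            out[combo] = p
    return out
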