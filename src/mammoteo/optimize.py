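"""Thermal Exchange Optimization (TEO) and its Advanced variant (ATEO).

TEO is a population metaheuristic modelled on Newton's law of cooling:
each candidate solution is a "temperature" vector that relaxes toward a
paired environment object, with the relaxation rate set by a cooling
factor derived from its cost.  The Advanced variant (ATEO) adds

* a best-guided exchange vector that rebuilds the worst member each
  iteration (differential-evolution-style crossover against the current
  best), and
* a self-adaptive population size that performs a bounded random walk,
  discarding the weakest members on shrink and injecting fresh uniform
  candidates on growth, never dropping below the problem dimension.

Elitism is provided by a thermal memory (TM): an archive of the best
candidates seen so far that is re-injected at the top of every iteration,
displacing an equal number of the worst members.  The best-so-far cost is
therefore monotone non-increasing in every run.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``TEOConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Candidate",
    "TEOConfig",
    "OptimizerState",
    "EvaluationError",
    "InvalidConfigError",
    "init_population",
    "cooling_factor",
    "time_value",
    "pair_objects",
    "env_temperature",
    "update_position",
    "component_perturbation",
    "ateo_exchange",
    "crossover_accept",
    "adapt_population_size",
    "run_ateo",
    "run_teo",
]


class InvalidConfigError(ValueError):
    """Raised for non-finite bounds, zero iteration budgets, etc."""


class EvaluationError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclass
class Candidate:
    """A position ("temperature") vector with its objective value."""

    position: np.ndarray
    cost: float

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.cost)


@dataclass
class TEOConfig:
    """Control parameters for TEO/ATEO.

    ``alpha1``/``alpha2`` weight the environment-temperature decay,
    ``gamma`` scales the exchange difference vector, ``cg`` is the
    crossover constant, ``pr`` the per-candidate perturbation
    probability, and ``tm_size`` the thermal-memory capacity (default
    ``ceil(PS/10)``).  ``pop_size`` overrides the default ``10*D``
    initial population.  ``exchange`` and ``adapt_population`` toggle
    the two ATEO extensions; with both off the loop is the plain TEO
    update.  ``perturbation_decay`` applies the ``exp(-zeta*t)`` factor
    to the component reset; switching it off reproduces the classic TEO
    component reset.
    """

    lower: Sequence[float] | float = -100.0
    upper: Sequence[float] | float = 100.0
    alpha1: float = 0.3
    alpha2: float = 0.3
    gamma: float = 0.5
    cg: float = 0.5
    pr: float = 0.3
    tm_size: Optional[int] = None
    pop_size: Optional[int] = None
    max_fes: int = 10_000
    error_floor: float = 0.0
    seed: int = 0
    perturbation_decay: bool = True
    exchange: bool = True
    adapt_population: bool = True
    vectorized: bool = False

    def bounds(self, d: int) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.lower, dtype=float), (d,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, dtype=float), (d,)).copy()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise InvalidConfigError("bounds must be finite")
        if np.any(lo >= hi):
            raise InvalidConfigError("each lower bound must be < upper bound")
        return lo, hi


@dataclass
class OptimizerState:
    """Population snapshot: positions are rows of ``positions``."""

    positions: np.ndarray
    costs: np.ndarray
    thermal_memory: List[Candidate] = field(default_factory=list)
    iteration: int = 0
    fe_count: int = 0
    best: Optional[Candidate] = None

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]

    def population(self) -> List[Candidate]:
        return [Candidate(p.copy(), float(c)) for p, c in zip(self.positions, self.costs)]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _evaluate(objective: Callable, X: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        costs = np.asarray(objective(X), dtype=float)
    else:
        costs = np.array([float(objective(x)) for x in X], dtype=float)
    if costs.shape != (X.shape[0],):
        raise EvaluationError("objective returned wrong shape")
    bad = ~np.isfinite(costs)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise EvaluationError(f"objective returned non-finite cost for candidate {X[i]}")
    return costs


def init_population(
    config: TEOConfig, d: int, rng: np.random.Generator, objective: Callable
) -> OptimizerState:
    """Draw the initial population uniformly within the bounds.

    Population size defaults to ``10*d`` unless ``config.pop_size``
    overrides it; every member is evaluated, so ``fe_count`` starts at
    the population size.
    """
    if d < 1:
        raise InvalidConfigError("dimension must be >= 1")
    lo, hi = config.bounds(d)
    ps = config.pop_size if config.pop_size is not None else 10 * d
    if ps < 2:
        raise InvalidConfigError("population size must be >= 2")
    theta = rng.random((ps, d))
    X = lo + theta * (hi - lo)
    costs = _evaluate(objective, X, config.vectorized)
    state = OptimizerState(positions=X, costs=costs, fe_count=ps)
    b = int(np.argmin(costs))
    state.best = Candidate(X[b].copy(), float(costs[b]))
    return state


def cooling_factor(cost: float, worst_cost: float) -> float:
    """Cooling rate ``zeta`` = cost / worst cost; 0 for a degenerate
    all-optimal population (worst cost 0)."""
    if worst_cost == 0:
        return 0.0
    return cost / worst_cost


def time_value(iteration: int, max_iteration: int) -> float:
    """Normalized time ``t`` = iteration / max_iteration in [0, 1]."""
    if max_iteration < 1:
        raise InvalidConfigError("max_iteration must be >= 1")
    if not 0 <= iteration <= max_iteration:
        raise ValueError("iteration outside [0, max_iteration]")
    return iteration / max_iteration


def pair_objects(n: int) -> np.ndarray:
    """Partner index for each of ``n`` rank-sorted members.

    Member ``i`` of the better half is the environment object for member
    ``n/2 + i`` and vice versa.  ``n`` must be even (the caller pads an
    odd population by duplicating the best member).
    """
    if n < 2:
        raise InvalidConfigError("need at least 2 members to pair")
    if n % 2:
        raise InvalidConfigError("population must be even for pairing")
    half = n // 2
    partner = np.empty(n, dtype=int)
    partner[:half] = np.arange(half) + half
    partner[half:] = np.arange(half)
    return partner


def env_temperature(
    prev_env: np.ndarray, alpha1: float, alpha2: float, t: float, delta: float | np.ndarray
) -> np.ndarray:
    """Decayed environment temperature ``(1 - (a1 + a2*(1-t))*delta) * prev``."""
    factor = 1.0 - (alpha1 + alpha2 * (1.0 - t)) * np.asarray(delta, dtype=float)
    return factor * np.asarray(prev_env, dtype=float)


def update_position(
    t_old: np.ndarray,
    t_env: np.ndarray,
    zeta: float,
    t: float,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Newton-cooling relaxation ``env + (old - env) * exp(-zeta*t)``."""
    out = t_env + (t_old - t_env) * math.exp(-zeta * t)
    if lower is not None:
        out = np.clip(out, lower, upper)
    return out


def component_perturbation(
    candidate: Candidate,
    config: TEOConfig,
    zeta: float,
    t: float,
    rng: np.random.Generator,
    d: Optional[int] = None,
) -> Candidate:
    """With probability ``pr`` reset one uniformly chosen dimension to a
    decayed uniform draw near the lower bound.

    The reset value is ``lower_j + delta*(upper_j - lower_j)*exp(-zeta*t)``
    (the decay factor is dropped when ``perturbation_decay`` is off).
    """
    d = d if d is not None else candidate.position.size
    lo, hi = config.bounds(d)
    if rng.random() >= config.pr:
        return candidate
    j = int(rng.integers(0, d))
    delta = rng.random()
    scale = math.exp(-zeta * t) if config.perturbation_decay else 1.0
    pos = candidate.position.copy()
    pos[j] = lo[j] + delta * (hi[j] - lo[j]) * scale
    pos[j] = min(max(pos[j], lo[j]), hi[j])
    return Candidate(pos, math.nan)


def ateo_exchange(
    best: Candidate,
    positions: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> Optional[np.ndarray]:
    """Exchange vector ``best + gamma*(T_r1 - T_r2)`` for the worst member.

    Returns ``None`` (skip signal) when fewer than 3 members are
    available to draw distinct ``r1 != r2`` plus the best.
    """
    n = positions.shape[0]
    if n < 3:
        return None
    r1, r2 = rng.choice(n, size=2, replace=False)
    vec = best.position + gamma * (positions[r1] - positions[r2])
    return np.clip(vec, lower, upper)


def crossover_accept(
    worst: Candidate,
    exchange: np.ndarray,
    cg: float,
    objective: Callable,
    rng: np.random.Generator,
    vectorized: bool = False,
) -> Tuple[Candidate, int]:
    """Per-dimension crossover of the exchange vector into the worst
    member; the trial replaces the worst only if its cost is lower.

    Returns the surviving candidate and the number of objective
    evaluations spent (0 when ``cg == 0`` produces an unchanged trial).
    """
    mask = rng.random(worst.position.size) < cg
    trial = np.where(mask, exchange, worst.position)
    if not mask.any():
        return worst, 0
    cost = float(_evaluate(objective, trial[None, :], vectorized)[0])
    if cost < worst.cost:
        return Candidate(trial, cost), 1
    return worst, 1


def adapt_population_size(
    positions: np.ndarray,
    costs: np.ndarray,
    d: int,
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    objective: Callable,
    vectorized: bool,
    fe_budget: int,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Random-walk resize: ``PS_new = round(PS + rnd*PS)``, ``rnd`` uniform
    on [-0.5, 0.5], floored at the problem dimension.

    Shrinking keeps the lowest-cost members; growing appends fresh
    uniform candidates (evaluated, spending from ``fe_budget``).
    Returns the new arrays and the number of evaluations used.
    """
    ps = positions.shape[0]
    rnd = rng.uniform(-0.5, 0.5)
    ps_new = int(round(ps + rnd * ps))
    ps_new = max(ps_new, d, 2)
    if ps_new == ps:
        return positions, costs, 0
    if ps_new < ps:
        keep = np.argsort(costs, kind="stable")[:ps_new]
        keep.sort()  # preserve current ordering among survivors
        return positions[keep], costs[keep], 0
    n_extra = min(ps_new - ps, fe_budget)
    if n_extra <= 0:
        return positions, costs, 0
    theta = rng.random((n_extra, d))
    fresh = lo + theta * (hi - lo)
    fresh_costs = _evaluate(objective, fresh, vectorized)
    return (
        np.vstack([positions, fresh]),
        np.concatenate([costs, fresh_costs]),
        n_extra,
    )


# ---------------------------------------------------------------------------
# the assembled loop
# ---------------------------------------------------------------------------


def _tm_capacity(config: TEOConfig, ps0: int) -> int:
    if config.tm_size is not None:
        return config.tm_size
    return max(1, math.ceil(ps0 / 10))


def _merge_thermal_memory(
    positions: np.ndarray, costs: np.ndarray, tm: List[Candidate]
) -> Tuple[np.ndarray, np.ndarray]:
    """Inject TM members at the expense of an equal number of worst
    members; arrays come in and leave sorted by cost."""
    if not tm:
        return positions, costs
    k = min(len(tm), positions.shape[0] - 1)
    if k <= 0:
        return positions, costs
    tm_pos = np.array([c.position for c in tm[:k]])
    tm_cost = np.array([c.cost for c in tm[:k]])
    positions = np.vstack([positions[: positions.shape[0] - k], tm_pos])
    costs = np.concatenate([costs[: costs.shape[0] - k], tm_cost])
    order = np.argsort(costs, kind="stable")
    return positions[order], costs[order]


def _update_tm(tm: List[Candidate], positions: np.ndarray, costs: np.ndarray, cap: int) -> List[Candidate]:
    pool = tm + [Candidate(positions[i].copy(), float(costs[i])) for i in range(min(cap, positions.shape[0]))]
    pool.sort(key=lambda c: c.cost)
    dedup: List[Candidate] = []
    for c in pool:
        if not any(c.cost == d.cost and np.array_equal(c.position, d.position) for d in dedup):
            dedup.append(c)
        if len(dedup) == cap:
            break
    return dedup


def run_ateo(
    objective: Callable,
    d: int,
    config: TEOConfig,
) -> Tuple[Candidate, "pd.DataFrame"]:
    """Run the optimizer and return (best candidate, history table).

    The history records (iteration, fe_count, best_cost, ps) once per
    iteration; ``best_cost`` is the best value ever evaluated and is
    monotone non-increasing.  Termination: ``fe_count >= max_fes`` or
    ``best_cost <= error_floor``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds(d)
    state = init_population(config, d, rng, objective)
    tm_cap = _tm_capacity(config, state.pop_size)
    best = state.best.copy()

    hist_rows = [(0, state.fe_count, best.cost, state.pop_size)]
    positions, costs = state.positions, state.costs
    iteration = 0
    fe_count = state.fe_count
    max_iter = max(1, math.ceil(config.max_fes / max(1, positions.shape[0])))
    tm: List[Candidate] = []

    while fe_count < config.max_fes and best.cost > config.error_floor:
        iteration += 1
        order = np.argsort(costs, kind="stable")
        positions, costs = positions[order], costs[order]

        positions, costs = _merge_thermal_memory(positions, costs, tm)
        tm = _update_tm(tm, positions, costs, tm_cap)

        ps = positions.shape[0]
        t = time_value(min(iteration, max_iter), max_iter)

        # pad an odd population with a copy of the best for pairing
        padded = ps % 2 == 1
        if padded:
            positions = np.vstack([positions, positions[0]])
            costs = np.concatenate([costs, costs[:1]])
        n = positions.shape[0]
        partner = pair_objects(n)

        worst_cost = float(costs[-1])
        zeta = np.zeros(n) if worst_cost == 0 else costs / worst_cost

        delta = rng.random(n)
        env = env_temperature(positions[partner], config.alpha1, config.alpha2, t, delta[:, None])
        decay = np.exp(-zeta * t)[:, None]
        new_pos = env + (positions - env) * decay
        new_pos = np.clip(new_pos, lo, hi)

        # component perturbation (vectorized draw per member)
        R = rng.random(n)
        dims = rng.integers(0, d, size=n)
        deltas = rng.random(n)
        scale = np.exp(-zeta * t) if config.perturbation_decay else np.ones(n)
        reset_vals = lo[dims] + deltas * (hi[dims] - lo[dims]) * scale
        hit = R < config.pr
        new_pos[hit, dims[hit]] = np.clip(reset_vals[hit], lo[dims[hit]], hi[dims[hit]])

        if padded:
            new_pos = new_pos[:-1]
            n = n - 1

        budget = config.max_fes - fe_count
        n_eval = min(n, budget)
        if n_eval > 0:
            evaluated = _evaluate(objective, new_pos[:n_eval], config.vectorized)
            positions = positions[:n]
            costs = costs[:n].copy()
            positions[:n_eval] = new_pos[:n_eval]
            costs[:n_eval] = evaluated
            fe_count += n_eval
        else:
            positions, costs = positions[:n], costs[:n]

        b = int(np.argmin(costs))
        if costs[b] < best.cost:
            best = Candidate(positions[b].copy(), float(costs[b]))

        # ATEO extension 1: best-guided exchange for the worst member
        if config.exchange and fe_count < config.max_fes and positions.shape[0] >= 3:
            vec = ateo_exchange(best, positions, config.gamma, rng, lo, hi)
            if vec is not None:
                w = int(np.argmax(costs))
                survivor, spent = crossover_accept(
                    Candidate(positions[w].copy(), float(costs[w])),
                    vec,
                    config.cg,
                    objective,
                    rng,
                    config.vectorized,
                )
                fe_count += spent
                positions[w] = survivor.position
                costs[w] = survivor.cost
                if survivor.cost < best.cost:
                    best = survivor.copy()

        # ATEO extension 2: self-adaptive population size
        if config.adapt_population:
            positions, costs, spent = adapt_population_size(
                positions, costs, d, rng, lo, hi, objective, config.vectorized,
                config.max_fes - fe_count,
            )
            fe_count += spent
            b = int(np.argmin(costs))
            if costs[b] < best.cost:
                best = Candidate(positions[b].copy(), float(costs[b]))
            max_iter = max(max_iter, iteration + max(1, math.ceil(
                (config.max_fes - fe_count) / max(1, positions.shape[0]))))

        hist_rows.append((iteration, fe_count, best.cost, positions.shape[0]))

    history = pd.DataFrame(hist_rows, columns=["iteration", "fe_count", "best_cost", "ps"])
    return best, history


def run_teo(objective: Callable, d: int, config: TEOConfig):
    """Plain TEO: the same cooling loop with both ATEO extensions off."""
    plain = replace(config, exchange=False, adapt_population=False)
    return run_ateo(objective, d, plain)
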