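"""Red-billed blue magpie optimization (RBMO) and its improved variant (IRBMO).

Both algorithms are population metaheuristics for continuous minimization
over a box ``[lb, ub]^D``.  RBMO alternates a small/large-group *search*
move with a food-guided *prey* move; IRBMO replaces these with an
elite-pool-guided search, a Cauchy/Levy collaborative hunt, and a
food-abundance-scheduled memory-compensation move.  Every candidate move
passes through greedy selection against the agent's retained (memory)
position, so the best-so-far fitness trajectory is monotone non-increasing
by construction.

The update rules are exposed as small pure functions of their stochastic
draws so they can be exercised deterministically; :func:`run_optimizer`
composes them with a seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import inspect
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OptimizerConfig",
    "SwarmState",
    "RunTrace",
    "cf_factor",
    "mantegna_sigma",
    "levy_step",
    "clamp",
    "greedy_select",
    "search_update",
    "prey_update",
    "elite_mean_update",
    "elite_brownian_update",
    "hunt_cauchy_update",
    "hunt_levy_update",
    "compensation_elite_update",
    "compensation_reserve_update",
    "initialize_population",
    "run_optimizer",
]

LEVY_BETA = 1.5


class ConfigurationError(ValueError):
    """Raised when an optimizer configuration violates its invariants."""


@dataclass
class OptimizerConfig:
    """Run settings for one RBMO/IRBMO optimization.

    Parameters
    ----------
    dim
        Problem dimensionality ``D``.
    lower_bound, upper_bound
        Box constraints; scalars are broadcast over all dimensions.
    pop_size
        Number of agents ``N`` (at least 4: the elite pool needs the top
        three plus one other agent).
    max_iter
        Iteration budget ``T``.
    behavior_switch
        Probability ``S`` of taking the first branch in each IRBMO
        behavior pair (elite-mean vs. Brownian, Cauchy vs. Levy).
    rbmo_switch
        Probability ``p`` of the small-group branch in RBMO's paired
        moves.
    small_group_range
        Inclusive range the small foraging-group size is drawn from.
    large_group_min
        Lower end of the large-group size range; the upper end is ``N``.
    seed
        Seed for the run's random generator.
    """

    dim: int
    lower_bound: float | Sequence[float] = 0.0
    upper_bound: float | Sequence[float] = 1.0
    pop_size: int = 30
    max_iter: int = 100
    behavior_switch: float = 0.5
    rbmo_switch: float = 0.5
    small_group_range: tuple[int, int] = (2, 5)
    large_group_min: int = 10
    seed: int = 0

    lb: np.ndarray = field(init=False, repr=False)
    ub: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError(
                f"pop_size must be >= 4 (elite pool of top-3 plus mean needs "
                f"a fourth agent), got {self.pop_size}"
            )
        if self.dim < 1:
            raise ConfigurationError(f"dim must be positive, got {self.dim}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be positive, got {self.max_iter}")
        self.lb = np.broadcast_to(np.asarray(self.lower_bound, dtype=float), (self.dim,)).copy()
        self.ub = np.broadcast_to(np.asarray(self.upper_bound, dtype=float), (self.dim,)).copy()
        if np.any(self.lb > self.ub):
            raise ConfigurationError("lower_bound exceeds upper_bound in some dimension")
        for name in ("behavior_switch", "rbmo_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        lo, hi = self.small_group_range
        if not (2 <= lo <= hi):
            raise ConfigurationError(f"invalid small_group_range {self.small_group_range}")


@dataclass
class SwarmState:
    """Mutable state of one optimizer run.

    ``positions``/``fitness`` hold each agent's retained (memory) solution
    — greedy selection writes back only improvements, so per-agent fitness
    is non-increasing over iterations.  ``elite_pool`` holds the three
    lowest-fitness positions of the current population plus their mean.
    """

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    elite_pool: np.ndarray
    t: int = 0

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]


@dataclass
class RunTrace:
    """Result of one optimizer run: incumbent and convergence curve."""

    best_position: np.ndarray
    best_fitness: float
    curve: np.ndarray
    n_evaluations: int


def cf_factor(t: int, T: int) -> float:
    """Conditioning factor ``CF = (1 - t/T)^(2t/T)``.

    Decays from 1 at ``t = 0`` to 0 at ``t = T`` and shrinks prey-step and
    compensation-step sizes as the run matures.
    """
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if not 0 <= t <= T:
        raise ValueError(f"t must lie in [0, {T}], got {t}")
    u = t / T
    if u == 0.0:
        return 1.0
    return (1.0 - u) ** (2.0 * u)


def mantegna_sigma(beta: float) -> float:
    """Scale of the numerator Gaussian in Mantegna's Levy-step construction."""
    if not 1.0 < beta <= 2.0:
        raise ValueError(f"beta must lie in (1, 2], got {beta}")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(beta: float, rng: np.random.Generator) -> float:
    """One heavy-tailed Levy-flight step ``u / |v|^(1/beta)`` (Mantegna).

    ``u ~ N(0, sigma_u^2)``, ``v ~ N(0, 1)``; with ``beta = 1.5`` the step
    distribution has infinite variance, producing occasional long jumps.
    """
    sigma = mantegna_sigma(beta)
    u = rng.normal(0.0, sigma)
    v = rng.normal(0.0, 1.0)
    return u / abs(v) ** (1.0 / beta)


def clamp(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Project a position back into the box, bound by violated bound."""
    return np.minimum(np.maximum(x, lb), ub)


def greedy_select(
    position_old: np.ndarray,
    fit_old: float,
    position_new: np.ndarray,
    fit_new: float,
) -> tuple[np.ndarray, float]:
    """Keep the lower-fitness solution; exact ties keep the incumbent."""
    if not (np.isfinite(fit_old) and np.isfinite(fit_new)):
        raise ValueError("greedy_select requires finite fitness values")
    if fit_new < fit_old:
        return position_new, fit_new
    return position_old, fit_old


# ---------------------------------------------------------------------------
# Pure update rules.  Each takes its stochastic draws explicitly; the run
# loop below supplies them from the generator.  None of these clamps — the
# caller owns the boundary contract.
# ---------------------------------------------------------------------------


def search_update(x_i: np.ndarray, group_mean: np.ndarray, x_rs: np.ndarray, rand: float) -> np.ndarray:
    """RBMO foraging move: step from the group mean past a random agent."""
    return x_i + rand * (group_mean - x_rs)


def prey_update(
    x_food: np.ndarray, group_mean: np.ndarray, x_rs: np.ndarray, cf: float, rand: float
) -> np.ndarray:
    """RBMO hunting move: contract toward the food (incumbent) position."""
    return x_food + cf * rand * (group_mean - x_rs)


def elite_mean_update(x_best: np.ndarray, x_eq: np.ndarray, x_r1: np.ndarray, rand: float) -> np.ndarray:
    """IRBMO elite search, mean branch: move off the incumbent toward the
    elite centroid relative to a random agent."""
    return x_best + rand * (x_eq - x_r1)


def elite_brownian_update(
    rs_draw: np.ndarray,
    x_best: np.ndarray,
    x_r1: np.ndarray,
    rb: np.ndarray,
    rand: float,
) -> np.ndarray:
    """IRBMO elite search, Brownian branch: jitter a drawn elite-pool member
    along the incumbent direction with a per-dimension N(0,1) factor."""
    return rs_draw + rb * rand * (x_best - x_r1)


def hunt_cauchy_update(x_best: np.ndarray, x_eq: np.ndarray, x_i: np.ndarray, cv: float) -> np.ndarray:
    """IRBMO collaborative hunt, encircling branch (Cauchy-scaled)."""
    return x_best + cv * (x_eq - x_i)


def hunt_levy_update(
    rs_draw: np.ndarray,
    x_best: np.ndarray,
    levy: float,
    rand: float,
    moderator: float,
) -> np.ndarray:
    """IRBMO collaborative hunt, re-encircling branch (Levy-scaled)."""
    return (rs_draw - x_best) * levy + rand * rs_draw * moderator


def compensation_elite_update(
    x_i: np.ndarray,
    cf: float,
    rs_draw: np.ndarray,
    rand: float,
    lb: np.ndarray,
    ub: np.ndarray,
    e: float,
) -> np.ndarray:
    """Memory compensation when food is abundant: elite-led perturbation."""
    return x_i + cf * (rs_draw + rand * (ub - lb)) * e


def compensation_reserve_update(
    x_i: np.ndarray,
    a: float,
    rand: float,
    x_idx1: np.ndarray,
    x_idx2: np.ndarray,
) -> np.ndarray:
    """Memory compensation when food is scarce: recombine two random agents."""
    return x_i + (a * (1.0 - rand) + rand) * (x_idx1 - x_idx2)


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------


def _as_agent_objective(objective: Callable) -> Callable[[np.ndarray, int], float]:
    """Accept ``f(x)`` or ``f(x, agent_index)`` objectives uniformly."""
    try:
        n_params = len(inspect.signature(objective).parameters)
    except (TypeError, ValueError):
        n_params = 1
    if n_params >= 2:
        return objective
    return lambda x, _i: objective(x)


def _elite_pool(positions: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Three lowest-fitness positions plus their mean (4 x D)."""
    top3 = np.argsort(fitness, kind="stable")[:3]
    elites = positions[top3]
    return np.vstack([elites, elites.mean(axis=0)])


def initialize_population(
    config: OptimizerConfig,
    rng: np.random.Generator,
    objective: Callable | None = None,
) -> SwarmState:
    """Draw ``N`` uniform positions in the box and evaluate them.

    With ``objective=None`` fitness is left at ``+inf`` placeholders
    replaced on first evaluation (useful for tests of geometry only).
    """
    n, d = config.pop_size, config.dim
    positions = rng.uniform(config.lb, config.ub, size=(n, d))
    fitness = np.full(n, np.inf)
    if objective is not None:
        obj = _as_agent_objective(objective)
        fitness = np.array([float(obj(positions[i], i)) for i in range(n)])
        if not np.all(np.isfinite(fitness)):
            raise ValueError("objective returned a non-finite fitness during initialization")
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
        elite_pool=_elite_pool(positions, fitness),
        t=0,
    )


def _group_mean(positions: np.ndarray, rng: np.random.Generator, lo: int, hi: int) -> np.ndarray:
    """Mean of a foraging group of size drawn uniformly from [lo, hi]."""
    n = positions.shape[0]
    lo = min(lo, n)
    hi = min(hi, n)
    size = int(rng.integers(lo, hi + 1))
    members = rng.choice(n, size=size, replace=False)
    return positions[members].mean(axis=0)


def run_optimizer(
    objective: Callable,
    config: OptimizerConfig,
    variant: str = "irbmo",
) -> RunTrace:
    """Minimize ``objective`` over the configured box with RBMO or IRBMO.

    Parameters
    ----------
    objective
        ``f(x) -> float`` or ``f(x, agent_index) -> float`` (the latter lets
        stateful wrappers such as flip-based binarization keep per-agent
        state).  Lower is better.
    config
        Run settings; ``config.seed`` fully determines the trace.
    variant
        ``"rbmo"`` or ``"irbmo"``.

    Returns
    -------
    RunTrace
        Best position/fitness and the per-iteration best-fitness curve
        (length ``max_iter + 1``, entry 0 is the post-initialization best).
    """
    if variant not in ("rbmo", "irbmo"):
        raise ValueError(f"unknown variant {variant!r}; expected 'rbmo' or 'irbmo'")
    obj = _as_agent_objective(objective)
    rng = np.random.default_rng(config.seed)
    state = initialize_population(config, rng, obj)
    n_evals = config.pop_size
    curve = np.empty(config.max_iter + 1)
    curve[0] = state.best_fitness

    def accept(i: int, candidate: np.ndarray) -> None:
        nonlocal n_evals
        candidate = clamp(candidate, config.lb, config.ub)
        try:
            fit = float(obj(candidate, i))
        except Exception as exc:  # surface the failing position
            raise RuntimeError(
                f"objective raised at iteration {state.t}, agent {i}"
            ) from exc
        n_evals += 1
        if not np.isfinite(fit):
            raise ValueError(f"objective returned non-finite fitness {fit}")
        pos, fit = greedy_select(state.positions[i], state.fitness[i], candidate, fit)
        state.positions[i] = pos
        state.fitness[i] = fit
        if fit < state.best_fitness:
            state.best_fitness = fit
            state.best_position = pos.copy()

    T = config.max_iter
    s_lo, s_hi = config.small_group_range
    for t in range(1, T + 1):
        state.t = t
        cf = cf_factor(t, T)
        a = 1.0 - t / T  # food abundance, high early / low late
        state.elite_pool = _elite_pool(state.positions, state.fitness)
        for i in range(config.pop_size):
            pos = state.positions[i]
            if variant == "rbmo":
                # search behavior: small vs large foraging group
                if rng.random() < config.rbmo_switch:
                    gm = _group_mean(state.positions, rng, s_lo, s_hi)
                else:
                    gm = _group_mean(state.positions, rng, config.large_group_min, config.pop_size)
                x_rs = state.positions[rng.integers(config.pop_size)]
                accept(i, search_update(pos, gm, x_rs, rng.random()))
                # prey behavior: food-guided contraction
                pos = state.positions[i]
                if rng.random() < config.rbmo_switch:
                    gm = _group_mean(state.positions, rng, s_lo, s_hi)
                else:
                    gm = _group_mean(state.positions, rng, config.large_group_min, config.pop_size)
                x_rs = state.positions[rng.integers(config.pop_size)]
                accept(i, prey_update(state.best_position, gm, x_rs, cf, rng.random()))
            else:
                # behavior 1: elite search
                x_r1 = state.positions[rng.integers(config.pop_size)]
                if rng.random() < config.behavior_switch:
                    cand = elite_mean_update(
                        state.best_position, state.elite_pool[3], x_r1, rng.random()
                    )
                else:
                    rs_draw = state.elite_pool[rng.integers(4)]
                    rb = rng.normal(0.0, 1.0, size=config.dim)
                    cand = elite_brownian_update(
                        rs_draw, state.best_position, x_r1, rb, rng.random()
                    )
                # behavior 2: collaborative hunt, chained off behavior 1
                cand = clamp(cand, config.lb, config.ub)
                if rng.random() < config.behavior_switch:
                    cv = rng.standard_cauchy()
                    cand = hunt_cauchy_update(state.best_position, state.elite_pool[3], cand, cv)
                else:
                    rs_draw = state.elite_pool[rng.integers(4)]
                    cand = hunt_levy_update(
                        rs_draw,
                        state.best_position,
                        levy_step(LEVY_BETA, rng),
                        rng.random(),
                        rng.random(),
                    )
                accept(i, cand)
                # behavior 3: memory compensation with second greedy acceptance
                pos = state.positions[i]
                if a > rng.random():
                    rs_draw = state.elite_pool[rng.integers(4)]
                    cand = compensation_elite_update(
                        pos, cf, rs_draw, rng.random(), config.lb, config.ub, rng.normal()
                    )
                else:
                    x_idx1 = state.positions[rng.integers(config.pop_size)]
                    x_idx2 = state.positions[rng.integers(config.pop_size)]
                    cand = compensation_reserve_update(pos, a, rng.random(), x_idx1, x_idx2)
                accept(i, cand)
        curve[t] = state.best_fitness

    return RunTrace(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        curve=curve,
        n_evaluations=n_evals,
    )
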