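"""Water Cycle Algorithm over mixed continuous/integer/categorical spaces.

A population of candidate solutions ("raindrops") is ranked by cost: the best
is the sea, the next best are rivers, the rest are streams.  Streams flow
toward their river and rivers toward the sea by

    X_new = X + U(0, 2) * (X_target - X),

with role exchange whenever a mover beats its target.  Rivers (and streams
assigned directly to the sea) that come within ``d_max`` of the sea evaporate
and rain back down as fresh uniform samples; ``d_max`` decays linearly to ~0
over the run, shifting the balance from exploration to exploitation.

Positions are handled internally on the unit cube (one axis per search
dimension, log-scaled where requested); integers are repaired by rounding and
categoricals by nearest index, and out-of-bounds moves are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "WCAConfig",
    "WCAResult",
    "Population",
    "initialize_population",
    "flow_step",
    "evaporate_and_rain",
    "wca_optimize",
]


@dataclass(frozen=True)
class Dimension:
    """One axis of a hyperparameter search space.

    kind is "continuous", "integer" or "categorical".  For continuous and
    integer axes ``lower < upper``; ``log=True`` samples and flows on the
    log scale (lower must then be > 0).  Categorical axes carry a nonempty
    ``categories`` tuple instead of bounds.
    """

    name: str
    kind: str = "continuous"
    lower: float | None = None
    upper: float | None = None
    categories: tuple | None = None
    log: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "categorical"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"categorical dimension {self.name!r} needs categories")
        else:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"dimension {self.name!r} needs lower < upper")
            if self.log and self.lower <= 0:
                raise ValueError(f"log-scale dimension {self.name!r} needs lower > 0")

    def decode(self, u: float):
        """Map a unit-cube coordinate to the dimension's native value."""
        u = min(max(u, 0.0), 1.0)
        if self.kind == "categorical":
            k = len(self.categories)
            return self.categories[min(int(u * k), k - 1)]
        if self.log:
            value = np.exp(np.log(self.lower) + u * (np.log(self.upper) - np.log(self.lower)))
        else:
            value = self.lower + u * (self.upper - self.lower)
        if self.kind == "integer":
            return int(np.clip(np.rint(value), self.lower, self.upper))
        return float(np.clip(value, self.lower, self.upper))


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of search dimensions."""

    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space needs at least one dimension")
        object.__setattr__(self, "dimensions", tuple(self.dimensions))

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def decode(self, u: np.ndarray) -> dict:
        """Unit-cube position -> {name: native value} mapping."""
        return {d.name: d.decode(ui) for d, ui in zip(self.dimensions, u)}

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(size=(size, self.ndim))


@dataclass(frozen=True)
class WCAConfig:
    """Control parameters of the optimizer.

    ``n_rivers_plus_sea`` (N_sr) counts the sea plus its rivers;
    ``d_max_initial`` is the evaporation distance threshold on the unit cube.
    """

    population_size: int = 30
    n_rivers_plus_sea: int = 4
    d_max_initial: float = 0.1
    max_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_size > self.n_rivers_plus_sea >= 1:
            raise ValueError("need population_size > n_rivers_plus_sea >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.d_max_initial <= 0:
            raise ValueError("d_max_initial must be > 0")


@dataclass
class WCAResult:
    """Best solution found plus the per-iteration convergence trace."""

    best_position: dict
    best_cost: float
    cost_history: np.ndarray
    evaluations: int
    final_population: list  # (decoded position dict, cost), best first


@dataclass
class Population:
    """Ranked raindrop population on the unit cube.

    Row 0 is the sea, rows 1..n_sr-1 the rivers, the rest streams.
    ``stream_target[i]`` gives, for stream row ``i`` (i >= n_sr), the row of
    the sea/river it flows toward.
    """

    positions: np.ndarray
    costs: np.ndarray
    n_sr: int
    stream_target: np.ndarray

    @property
    def size(self) -> int:
        return len(self.costs)

    def roles(self) -> list[str]:
        return ["sea"] + ["river"] * (self.n_sr - 1) + ["stream"] * (self.size - self.n_sr)


def _safe_cost(objective: Callable[[dict], float], space: SearchSpace, u: np.ndarray) -> float:
    value = objective(space.decode(u))
    value = float(value)
    return value if np.isfinite(value) else np.inf


def _allocate_streams(costs: np.ndarray, n_sr: int, n_streams: int) -> np.ndarray:
    """Assign each stream a sea/river row, streams per row ~ cost intensity.

    Better (lower-cost) seas/rivers attract more streams; counts always sum
    to the number of streams (largest-remainder rounding, leftovers to the
    sea).
    """
    selected = costs[:n_sr]
    finite = selected[np.isfinite(selected)]
    worst = finite.max() if finite.size else 0.0
    intensity = np.where(np.isfinite(selected), worst - selected, 0.0) + 1e-12
    share = intensity / intensity.sum() * n_streams
    counts = np.floor(share).astype(int)
    remainder = n_streams - counts.sum()
    if remainder > 0:
        order = np.argsort(-(share - counts), kind="stable")
        counts[order[:remainder]] += 1
    return np.repeat(np.arange(n_sr), counts)


def _rank(pop: Population) -> Population:
    """Re-sort the population by cost and re-allocate streams."""
    order = np.argsort(pop.costs, kind="stable")
    positions = pop.positions[order]
    costs = pop.costs[order]
    stream_target = _allocate_streams(costs, pop.n_sr, pop.size - pop.n_sr)
    return Population(positions, costs, pop.n_sr, stream_target)


def initialize_population(
    space: SearchSpace, config: WCAConfig, objective: Callable[[dict], float]
) -> tuple[Population, np.random.Generator, int]:
    """Sample the initial raindrops, evaluate them, and assign roles."""
    rng = np.random.default_rng(config.seed)
    positions = space.sample(rng, config.population_size)
    costs = np.array([_safe_cost(objective, space, u) for u in positions])
    if not np.isfinite(costs).any():
        raise RuntimeError("objective is non-finite on every initial raindrop")
    pop = _rank(Population(positions, costs, config.n_rivers_plus_sea, np.empty(0, int)))
    return pop, rng, config.population_size


def flow_step(
    pop: Population,
    rng: np.random.Generator,
    space: SearchSpace,
    objective: Callable[[dict], float],
    c: float = 2.0,
) -> tuple[Population, int]:
    """One round of stream->river and river->sea flow with role exchange."""
    positions = pop.positions.copy()
    costs = pop.costs.copy()
    n_sr = pop.n_sr
    evals = 0

    for i in range(n_sr, pop.size):  # streams
        target = pop.stream_target[i - n_sr]
        step = rng.uniform(0.0, c)
        new = np.clip(positions[i] + step * (positions[target] - positions[i]), 0.0, 1.0)
        cost = _safe_cost(objective, space, new)
        evals += 1
        positions[i], costs[i] = new, cost
        if cost < costs[target]:
            positions[[i, target]] = positions[[target, i]]
            costs[[i, target]] = costs[[target, i]]

    for i in range(1, n_sr):  # rivers flow to the sea
        step = rng.uniform(0.0, c)
        new = np.clip(positions[i] + step * (positions[0] - positions[i]), 0.0, 1.0)
        cost = _safe_cost(objective, space, new)
        evals += 1
        positions[i], costs[i] = new, cost
        if cost < costs[0]:
            positions[[i, 0]] = positions[[0, i]]
            costs[[i, 0]] = costs[[0, i]]

    return _rank(Population(positions, costs, n_sr, pop.stream_target)), evals


def evaporate_and_rain(
    pop: Population,
    d_max_current: float,
    config: WCAConfig,
    rng: np.random.Generator,
    space: SearchSpace,
    objective: Callable[[dict], float],
) -> tuple[Population, float, int]:
    """Re-seed drops that crowd the sea; decay the evaporation threshold.

    Rivers, and streams assigned directly to the sea, closer than
    ``d_max_current`` to the sea are replaced by fresh uniform samples.
    Returns the updated population, the decayed threshold, and the number of
    objective evaluations spent.
    """
    positions = pop.positions.copy()
    costs = pop.costs.copy()
    n_sr = pop.n_sr
    evals = 0

    candidates = list(range(1, n_sr)) + [
        n_sr + j for j, t in enumerate(pop.stream_target) if t == 0
    ]
    for i in candidates:
        if np.linalg.norm(positions[0] - positions[i]) < d_max_current:
            positions[i] = rng.uniform(size=space.ndim)
            costs[i] = _safe_cost(objective, space, positions[i])
            evals += 1

    d_max_next = d_max_current - d_max_current / config.max_iterations
    pop = _rank(Population(positions, costs, n_sr, pop.stream_target))
    return pop, d_max_next, evals


def wca_optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    config: WCAConfig = WCAConfig(),
) -> WCAResult:
    """Minimize ``objective`` over ``space`` with the water cycle algorithm.

    The objective receives a ``{name: value}`` dict and returns a finite cost
    (non-finite values are treated as +inf).  Deterministic for a fixed
    ``config.seed``; the returned ``cost_history`` (best cost ever, per
    iteration) is non-increasing.
    """
    pop, rng, evals = initialize_population(space, config, objective)
    best_u = pop.positions[0].copy()
    best_cost = float(pop.costs[0])
    history = [best_cost]
    d_max = config.d_max_initial

    for _ in range(config.max_iterations):
        pop, e1 = flow_step(pop, rng, space, objective)
        pop, d_max, e2 = evaporate_and_rain(pop, d_max, config, rng, space, objective)
        evals += e1 + e2
        if pop.costs[0] < best_cost:
            best_cost = float(pop.costs[0])
            best_u = pop.positions[0].copy()
        history.append(best_cost)

    final = [(space.decode(u), float(c)) for u, c in zip(pop.positions, pop.costs)]
    return WCAResult(
        best_position=space.decode(best_u),
        best_cost=best_cost,
        cost_history=np.asarray(history),
        evaluations=evals,
        final_population=final,
    )
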