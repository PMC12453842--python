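"""Stage 2: crow search over feature masks.

Each crow carries a continuous position vector inside the box
``[lower_bound, upper_bound]^L_t``; the feature mask it represents is read
off by thresholding (bit = 1 iff the coordinate is >= ``init_threshold``,
the same operation that creates the initial positions from uniform draws, so
the initial selection density is 0.6 at the default threshold 0.4).
Keeping the coordinates continuous between evaluations is what lets flights
cross the threshold gradually and drop as well as add individual features;
a strictly 0/1 position encoding would freeze every coordinate on which a
crow and its followed memory agree and could never shrink a subset below
its initial density.

Two optimizers share one evaluation loop:

* :func:`run_classic_csa` — the classic crow search algorithm.  Per crow a
  uniform draw ``R_i`` picks the branch: if ``R_i >= AP`` the crow flies
  toward a uniformly random other crow's memory,
  ``v = X + R_i * fl * (M_j - X)``; otherwise it jumps to a fresh uniform
  random position.

* :func:`run_icsa` — the improved variant: the uniform draw is replaced by
  a chaotic sequence ``C_1 = 0.7, C_{k+1} = sin(pi * C_k)`` shared by all
  crows within an iteration; the awareness probability is dynamic per crow,
  ``DAP = AP_min + (AP_max - AP_min) * fitness / min_fitness_seen`` clipped
  to ``[AP_min, AP_max]``; the followed memory comes from a fitness-sorted
  neighbourhood (the six crows ranked just below, plus a random crow and its
  three-chain), taking the best memory in that set; and the global move is
  experience-guided — the new position keeps the crow's own memory on a
  random 80% of the coordinates (the current-optimal part) and re-draws the
  remaining ``explore_fraction`` = 20% uniformly (the exploration part),
  instead of jumping blindly.

Memories update only on strict fitness improvement, so each crow's memory
fitness is non-decreasing and the returned best is the maximum memory over
all crows and iterations.  Everything is reproducible from
(data, config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .fitness import FitnessContext, FitnessValue, fitness

__all__ = ["ICSAConfig", "CrowState", "ChaoticSequence", "SelectionResult",
           "chaotic_step", "dynamic_awareness", "initialize_population",
           "assign_neighbors", "local_update", "global_update",
           "update_memory", "run_icsa", "run_classic_csa"]


@dataclass
class ICSAConfig:
    """Search hyperparameters.

    Defaults are the reference operating point: population ``n_crows=10``,
    ``max_iter=30`` iterations, flight length 2, position bounds [0, 1],
    binarization/init threshold 0.4 (initial bit density 0.6), awareness
    bounds 0.1/0.9, a 20% exploration subset in the global move, and a
    6-local + 1+3-chain neighbourhood.
    """

    n_crows: int = 10
    max_iter: int = 30
    flight_length: float = 2.0
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    init_threshold: float = 0.4
    ap_min: float = 0.1
    ap_max: float = 0.9
    explore_fraction: float = 0.2
    n_local_neighbors: int = 6
    n_global_chain: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crows < 1:
            raise ValueError("n_crows must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.init_threshold <= 1.0:
            raise ValueError("init_threshold must be in [0, 1]")
        if not self.ap_min < self.ap_max:
            raise ValueError("ap_min must be < ap_max")
        if not 0.0 < self.explore_fraction < 1.0:
            raise ValueError("explore_fraction must be in (0, 1)")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")


@dataclass
class CrowState:
    """One crow: continuous position and memory vectors, their fitnesses,
    and the historical minimum total fitness (the dynamic-awareness
    denominator).  The masks the vectors encode are exposed as properties."""

    position: np.ndarray
    memory: np.ndarray
    position_fitness: FitnessValue
    memory_fitness: FitnessValue
    min_fitness_seen: float
    threshold: float = 0.4

    @property
    def position_mask(self) -> np.ndarray:
        return self.position >= self.threshold

    @property
    def memory_mask(self) -> np.ndarray:
        return self.memory >= self.threshold


class ChaoticSequence:
    """Sine chaotic map: emits 0.7 first, then iterates c -> sin(pi * c).

    The trajectory from 0.7 stays in [0, 1] (sin of an angle in [0, pi])."""

    def __init__(self) -> None:
        self.current = 0.7
        self.k = 1

    def step(self) -> float:
        value = self.current
        self.current = math.sin(math.pi * self.current)
        self.k += 1
        return value


def chaotic_step(seq: ChaoticSequence) -> float:
    """Return the chaotic value for the current iteration and advance."""
    return seq.step()


def dynamic_awareness(position_total: float, min_fitness_seen: float,
                      ap_min: float, ap_max: float) -> float:
    """Dynamic awareness probability, clipped into ``[ap_min, ap_max]``.

    The raw value is ``ap_min + (ap_max - ap_min) * total / min_seen``; with
    positive fitness the ratio is >= 1, so without clipping the value would
    saturate above ``ap_max`` — the clip keeps both branches reachable."""
    if min_fitness_seen <= 0:
        raise ValueError("dynamic awareness needs a positive fitness history")
    raw = ap_min + (ap_max - ap_min) * (position_total / min_fitness_seen)
    return float(min(max(raw, ap_min), ap_max))


def _mask_of(vec: np.ndarray, config: ICSAConfig) -> np.ndarray:
    return vec >= config.init_threshold


def _repair(vec: np.ndarray, config: ICSAConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Masks must be non-empty: raise one random coordinate to the upper
    bound if the vector encodes the empty mask."""
    if not (vec >= config.init_threshold).any():
        vec = vec.copy()
        vec[rng.integers(vec.size)] = config.upper_bound
    return vec


def _random_position(L_t: int, config: ICSAConfig,
                     rng: np.random.Generator) -> np.ndarray:
    span = config.upper_bound - config.lower_bound
    return _repair(config.lower_bound + span * rng.random(L_t), config, rng)


def initialize_population(ctx: FitnessContext, config: ICSAConfig,
                          rng: np.random.Generator) -> list[CrowState]:
    """Uniform random position vectors thresholded into masks: each bit is 1
    with probability 1 - init_threshold (0.6 at the default 0.4); memory
    starts at the position."""
    crows = []
    for _ in range(config.n_crows):
        pos = _random_position(ctx.L_t, config, rng)
        fit = fitness(ctx, _mask_of(pos, config))
        crows.append(CrowState(position=pos, memory=pos.copy(),
                               position_fitness=fit, memory_fitness=fit,
                               min_fitness_seen=fit.total,
                               threshold=config.init_threshold))
    return crows


def assign_neighbors(n_crows: int, i: int, config: ICSAConfig,
                     rng: np.random.Generator) -> list[int]:
    """Neighbour ranks for crow ``i`` in the fitness-sorted population.

    Local: ranks ``i+1 .. i+n_local`` wrapping modulo the population size and
    excluding ``i``.  Global: a random rank ``j`` plus its chain
    ``j+1 .. j+n_chain`` (wrapping, excluding ``i``).  Duplicates removed,
    order preserved; for small populations the set is simply all other
    crows."""
    if n_crows < 2:
        raise ValueError("need at least 2 crows to assign neighbours")
    ranks: list[int] = []
    for step in range(1, config.n_local_neighbors + 1):
        r = (i + step) % n_crows
        if r != i and r not in ranks:
            ranks.append(r)
    j = int(rng.integers(n_crows - 1))
    j += j >= i  # uniform over ranks != i
    for step in range(0, config.n_global_chain + 1):
        r = (j + step) % n_crows
        if r != i and r not in ranks:
            ranks.append(r)
    return ranks


def local_update(position: np.ndarray, followed_memory: np.ndarray,
                 coeff: float, config: ICSAConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Fly toward a memory: ``v = X + coeff * fl * (M - X)`` per coordinate,
    clipped to the bounds; repaired if the encoded mask is empty.

    ``coeff`` is the chaotic value (improved variant) or the uniform draw
    ``R_i`` (classic variant).  ``coeff * fl = 1`` lands exactly on the
    followed memory."""
    v = position + coeff * config.flight_length * (followed_memory - position)
    np.clip(v, config.lower_bound, config.upper_bound, out=v)
    return _repair(v, config, rng)


def global_update(memory: np.ndarray, config: ICSAConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Experience-guided global move.

    The new position consists of two parts: a uniformly random
    ``ceil(explore_fraction * L_t)`` coordinate subset is re-drawn uniformly
    within the bounds (the exploration part), while every other coordinate
    keeps the crow's memory value (the current-optimal part).  Features
    outside the explored subset therefore never change state, and explored
    features land selected with probability 1 - init_threshold."""
    L_t = memory.size
    n_explore = math.ceil(config.explore_fraction * L_t)
    explore = rng.choice(L_t, size=n_explore, replace=False)
    span = config.upper_bound - config.lower_bound
    new = memory.copy()
    new[explore] = config.lower_bound + span * rng.random(n_explore)
    return _repair(new, config, rng)


def update_memory(crow: CrowState, new_position: np.ndarray,
                  new_fitness: FitnessValue) -> CrowState:
    """Accept the new position; replace the memory only on strict fitness
    improvement; track the historical minimum total fitness."""
    crow.position = new_position
    crow.position_fitness = new_fitness
    if new_fitness.total > crow.memory_fitness.total:
        crow.memory = new_position.copy()
        crow.memory_fitness = new_fitness
    crow.min_fitness_seen = min(crow.min_fitness_seen, new_fitness.total)
    return crow


@dataclass
class SelectionResult:
    """Outcome of a search run.

    ``mask`` is over the ORIGINAL feature axis (length N) when the search ran
    on a pre-screened subspace; ``history`` carries per-iteration traces
    (best memory fitness, mean position fitness, best-memory subset size)."""

    mask: np.ndarray
    best_fitness: FitnessValue
    history: dict = field(default_factory=dict)
    config: ICSAConfig | None = None
    seed: int | None = None
    algorithm: str = "icsa"
    feature_names: list[str] | None = None
    search_space: int = 0

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_names(self) -> list[str] | None:
        if self.feature_names is None:
            return None
        return [self.feature_names[i] for i in self.selected_indices]

    def to_json(self) -> str:
        payload = {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "search_space": self.search_space,
            "n_selected": self.n_selected,
            "best_fitness": {
                "total": self.best_fitness.total,
                "acc": self.best_fitness.acc,
                "penalty_reward": self.best_fitness.penalty_reward,
                "L_s": self.best_fitness.L_s,
                "L_t": self.best_fitness.L_t,
            },
            "selected": (self.selected_names()
                         if self.feature_names is not None
                         else self.selected_indices.tolist()),
            "history": {k: list(map(float, v))
                        for k, v in self.history.items()},
            "config": asdict(self.config) if self.config else None,
        }
        return json.dumps(payload, indent=2)


def _finalize(crows, ctx, config, history, algorithm,
              feature_indices, n_original, feature_names) -> SelectionResult:
    best = max(crows, key=lambda c: c.memory_fitness.total)
    best_mask = best.memory_mask
    if feature_indices is None:
        mask = best_mask.copy()
    else:
        mask = np.zeros(n_original, dtype=bool)
        mask[np.asarray(feature_indices)[best_mask]] = True
    return SelectionResult(mask=mask, best_fitness=best.memory_fitness,
                           history=history, config=config, seed=config.seed,
                           algorithm=algorithm, feature_names=feature_names,
                           search_space=ctx.L_t)


def _sort_crows(crows: list[CrowState]) -> list[CrowState]:
    # descending position fitness; stable, so ties keep list order
    return sorted(crows, key=lambda c: -c.position_fitness.total)


def _record(history, crows):
    mem_totals = [c.memory_fitness.total for c in crows]
    pos_totals = [c.position_fitness.total for c in crows]
    best = int(np.argmax(mem_totals))
    history["best_fitness"].append(max(mem_totals))
    history["mean_fitness"].append(float(np.mean(pos_totals)))
    history["best_size"].append(int(crows[best].memory_mask.sum()))


def _run(ctx: FitnessContext, config: ICSAConfig, improved: bool,
         awareness: float | None, feature_indices, n_original,
         feature_names) -> SelectionResult:
    rng = np.random.default_rng(config.seed)
    crows = initialize_population(ctx, config, rng)
    chaos = ChaoticSequence()
    history = {"best_fitness": [], "mean_fitness": [], "best_size": []}
    for _k in range(config.max_iter):
        crows = _sort_crows(crows)
        c_k = chaotic_step(chaos) if improved else None
        for i, crow in enumerate(crows):
            if improved:
                dap = dynamic_awareness(crow.position_fitness.total,
                                        crow.min_fitness_seen,
                                        config.ap_min, config.ap_max)
                if c_k >= dap:
                    if config.n_crows >= 2:
                        nbrs = assign_neighbors(config.n_crows, i, config, rng)
                        j = max(nbrs,
                                key=lambda r: crows[r].memory_fitness.total)
                        followed = crows[j].memory
                    else:
                        followed = crow.memory
                    new_pos = local_update(crow.position, followed, c_k,
                                           config, rng)
                else:
                    new_pos = global_update(crow.memory, config, rng)
            else:
                r_i = float(rng.random())
                if r_i >= awareness:
                    if config.n_crows >= 2:
                        j = int(rng.integers(config.n_crows - 1))
                        j += j >= i
                        followed = crows[j].memory
                    else:
                        followed = crow.memory
                    new_pos = local_update(crow.position, followed, r_i,
                                           config, rng)
                else:
                    new_pos = _random_position(ctx.L_t, config, rng)
            update_memory(crow, new_pos,
                          fitness(ctx, _mask_of(new_pos, config)))
        _record(history, crows)
    return _finalize(crows, ctx, config, history,
                     "icsa" if improved else "csa",
                     feature_indices, n_original, feature_names)


def run_icsa(ctx: FitnessContext, config: ICSAConfig | None = None,
             feature_indices=None, n_original: int | None = None,
             feature_names: list[str] | None = None) -> SelectionResult:
    """Run the improved crow search on a fitness context.

    ``feature_indices`` maps the search-space axis back to original feature
    indices (length ``ctx.L_t``); when given, the result mask has length
    ``n_original``."""
    config = config or ICSAConfig()
    if feature_indices is not None and n_original is None:
        raise ValueError("n_original is required with feature_indices")
    return _run(ctx, config, True, None, feature_indices, n_original,
                feature_names)


def run_classic_csa(ctx: FitnessContext, config: ICSAConfig | None = None,
                    awareness: float = 0.1, feature_indices=None,
                    n_original: int | None = None,
                    feature_names: list[str] | None = None) -> SelectionResult:
    """Run the classic crow search baseline with constant awareness
    probability ``awareness``."""
    config = config or ICSAConfig()
    if not 0.0 <= awareness <= 1.0:
        raise ValueError("awareness must be in [0, 1]")
    if feature_indices is not None and n_original is None:
        raise ValueError("n_original is required with feature_indices")
    return _run(ctx, config, False, awareness, feature_indices, n_original,
                feature_names)
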