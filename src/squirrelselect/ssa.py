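"""Continuous squirrel search algorithm (SSA).

SSA is a population-based metaheuristic for box-constrained minimization.
Each candidate solution is a "flying squirrel" perched on a food tree; at a
role refresh the squirrel with the lowest objective value sits on the single
hickory tree, the next best few on acorn trees, and the remainder on normal
trees.  Each iteration, acorn squirrels glide toward the hickory squirrel and
normal squirrels glide toward either an acorn squirrel or the hickory
squirrel, covering a random gliding distance; with probability ``Pdp`` a
predator appears and the glide is replaced by a uniform random relocation.
When every acorn squirrel has drifted very close to the hickory squirrel
(the "seasonal" condition), winter is declared and the normal squirrels are
scattered by a Lévy flight to re-diversify the search.

Randomness contract
-------------------
A single seeded :class:`numpy.random.Generator` drives a run and every
stochastic draw consumes from it in a fixed, documented order (see
:func:`run_ssa`), so unit tests can script the stream and hand-unroll an
iteration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .config import SSAConfig

__all__ = [
    "HICKORY",
    "ACORN",
    "NORMAL",
    "GlideSample",
    "Population",
    "assign_roles",
    "initialize_population",
    "sample_glide",
    "update_acorn_towards_hickory",
    "update_normal_towards_acorn",
    "update_normal_towards_hickory",
    "seasonal_constant",
    "season_threshold",
    "winter_relocate",
    "run_ssa",
    "SquirrelSearch",
]

HICKORY = "hickory"
ACORN = "acorn"
NORMAL = "normal"

#: Lévy-flight stability exponent used for winter relocation.
LEVY_BETA = 1.5


@dataclass
class GlideSample:
    """One draw of the aerodynamic glide model.

    ``tan_phi = drag / lift`` is the glide angle's tangent and
    ``distance = hg / (tan_phi * sf)`` the resulting gliding distance,
    the step-length scalar of a directed move.
    """

    lift: float
    drag: float
    tan_phi: float
    distance: float


@dataclass
class Population:
    """State of the squirrel population during a run.

    ``positions`` is the N x D matrix of squirrel locations, ``fitness`` the
    objective values (lower is better), ``roles`` the tree assignment of each
    squirrel, and ``best_position`` / ``best_fitness`` the elitist best-ever
    solution.
    """

    positions: np.ndarray
    fitness: np.ndarray
    roles: np.ndarray
    iteration: int
    best_position: np.ndarray
    best_fitness: float

    @property
    def n_squirrels(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def indices_of(self, role: str) -> np.ndarray:
        """Ascending population indices of the squirrels with ``role``."""
        return np.flatnonzero(self.roles == role)


def _evaluate(fitness_fn: Callable, positions: np.ndarray, context: str) -> np.ndarray:
    values = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        v = float(fitness_fn(x))
        if not np.isfinite(v):
            raise ValueError(f"non-finite fitness {v!r} for squirrel {i} ({context})")
        values[i] = v
    return values


def assign_roles(population: Population, config: SSAConfig) -> None:
    """Refresh tree roles in place by fitness rank.

    The ``n_hickory`` best squirrels become hickory, the next ``n_acorn``
    acorn, the rest normal.  Ties are broken by population index (stable
    sort), so role assignment is deterministic.
    """
    order = np.argsort(population.fitness, kind="stable")
    roles = np.full(population.n_squirrels, NORMAL, dtype="<U7")
    roles[order[: config.n_hickory]] = HICKORY
    roles[order[config.n_hickory : config.n_hickory + config.n_acorn]] = ACORN
    population.roles = roles


def initialize_population(
    config: SSAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    dim: int,
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw the initial population uniformly inside the bounds.

    Each component is ``FSl + u * (FSu - FSl)`` with ``u`` uniform in
    ``[0, 1)``; the stream is consumed row by row (squirrel 0's D components
    first).  Fitness is evaluated, roles assigned by rank, and the elitist
    best recorded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds(dim)
    u = rng.uniform(0.0, 1.0, size=(config.n_squirrels, dim))
    positions = lo + u * (hi - lo)
    fitness = _evaluate(fitness_fn, positions, "initialization")
    best = int(np.argmin(fitness))
    pop = Population(
        positions=positions,
        fitness=fitness,
        roles=np.full(config.n_squirrels, NORMAL, dtype="<U7"),
        iteration=0,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
    )
    assign_roles(pop, config)
    return pop


def sample_glide(config: SSAConfig, rng: np.random.Generator) -> GlideSample:
    """Sample a gliding distance from the aerodynamic lift/drag model.

    Consumes one uniform draw: the lift coefficient ``CL`` over
    ``lift_coeff_range``.  Then ``tan_phi = CD / CL`` and
    ``distance = hg / (tan_phi * sf)``.  With the default constants
    (``CD = 0.60``, ``CL`` in ``[0.675, 1.5]``, ``hg = 8``, ``sf = 18``)
    the distance lies in ``[0.5, 1.1112]``.
    """
    lo, hi = config.lift_coeff_range
    lift = float(rng.uniform(lo, hi))
    tan_phi = config.drag_coeff / lift
    distance = config.glide_height / (tan_phi * config.scaling_factor)
    return GlideSample(lift=lift, drag=config.drag_coeff, tan_phi=tan_phi, distance=distance)


def _directed_move(
    position: np.ndarray,
    target: np.ndarray,
    glide: GlideSample,
    config: SSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared movement rule behind the three role-specific updates.

    Consumes one uniform draw ``R``.  If ``R >= Pdp`` (predator absent) the
    squirrel glides: ``new = position + dg * Gc * (target - position)``;
    otherwise it relocates uniformly inside the bounds (D further uniform
    draws).  The result is clamped to the bounds componentwise.
    """
    position = np.asarray(position, dtype=float)
    target = np.asarray(target, dtype=float)
    if position.shape != target.shape:
        raise ValueError(
            f"dimension mismatch: position has shape {position.shape}, target {target.shape}"
        )
    lo, hi = config.bounds(position.shape[0])
    r = float(rng.uniform(0.0, 1.0))
    if r >= config.predator_prob:
        new = position + glide.distance * config.gliding_constant * (target - position)
    else:
        new = np.asarray(rng.uniform(lo, hi), dtype=float)
    return np.clip(new, lo, hi)


def update_acorn_towards_hickory(pos_at, pos_ht, glide, config, rng) -> np.ndarray:
    """Move an acorn-tree squirrel toward the hickory squirrel (draw R1)."""
    return _directed_move(pos_at, pos_ht, glide, config, rng)


def update_normal_towards_acorn(pos_nt, pos_at, glide, config, rng) -> np.ndarray:
    """Move a normal-tree squirrel toward an acorn squirrel (draw R2)."""
    return _directed_move(pos_nt, pos_at, glide, config, rng)


def update_normal_towards_hickory(pos_nt, pos_ht, glide, config, rng) -> np.ndarray:
    """Move a normal-tree squirrel toward the hickory squirrel (draw R3)."""
    return _directed_move(pos_nt, pos_ht, glide, config, rng)


def seasonal_constant(acorn_positions: np.ndarray, hickory_position: np.ndarray) -> np.ndarray:
    """Per-acorn Euclidean distance to the hickory squirrel.

    ``Sc_i = sqrt(sum_k (FS_at[i,k] - FS_ht[k])**2)``; the seasonal monitor
    declares winter when the smallest of these falls below the shrinking
    threshold of :func:`season_threshold`.
    """
    acorn_positions = np.atleast_2d(np.asarray(acorn_positions, dtype=float))
    if acorn_positions.size == 0:
        raise ValueError("seasonal constant needs at least one acorn squirrel")
    hickory_position = np.asarray(hickory_position, dtype=float)
    return np.linalg.norm(acorn_positions - hickory_position, axis=1)


def season_threshold(iteration: int, max_iterations: int, scale: float = 1e-5) -> float:
    """Shrinking winter threshold ``Smin(t) = scale / 365**(t / (T/2.5))``."""
    if max_iterations <= 0:
        return scale
    return scale / 365.0 ** (iteration / (max_iterations / 2.5))


def _levy_step(dim: int, rng: np.random.Generator, beta: float = LEVY_BETA) -> np.ndarray:
    """Mantegna-recipe Lévy step of stability ``beta`` (2D normal draws)."""
    sigma = (
        _gamma(1 + beta)
        * np.sin(np.pi * beta / 2)
        / (_gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    return 0.01 * u / np.abs(v) ** (1 / beta)


def winter_relocate(config: SSAConfig, rng: np.random.Generator, dim: int) -> np.ndarray:
    """Relocate a squirrel after winter by a Lévy flight from the lower bound.

    Returns ``FSl + levy_step * (FSu - FSl)`` clamped to the bounds; with
    degenerate zero-width bounds this is ``FSl`` itself.  Consumes 2*D
    standard-normal draws.
    """
    lo = np.broadcast_to(np.asarray(config.lower_bound, dtype=float), (dim,))
    hi = np.broadcast_to(np.asarray(config.upper_bound, dtype=float), (dim,))
    new = lo + _levy_step(dim, rng) * (hi - lo)
    return np.clip(new, lo, hi)


def run_ssa(
    config: SSAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    dim: int,
    rng: np.random.Generator | None = None,
) -> tuple[Population, pd.DataFrame]:
    """Run the squirrel search loop and return the final population and trace.

    The trace has one row per iteration with columns ``iteration``,
    ``best_fitness`` (elitist, hence non-increasing), ``mean_fitness`` and
    ``winter_triggered``.

    Draw order per iteration (after the draws of
    :func:`initialize_population`):

    1. roles are refreshed by fitness rank (no draws);
    2. for each acorn squirrel in ascending population index: one lift
       coefficient (glide), one predator draw ``R1`` and, if the predator
       appears, D relocation uniforms;
    3. one permutation of the normal squirrels' indices; the first
       ``floor(n_normal / 2)`` entries glide toward an acorn squirrel, the
       rest toward the hickory squirrel;
    4. for each normal squirrel in ascending population index: if it heads
       for an acorn tree, one integer draw choosing the acorn squirrel, then
       one lift coefficient and one predator draw (``R2`` / ``R3``) plus
       any relocation uniforms;
    5. if the seasonal condition triggers winter: for each normal squirrel in
       ascending index, 2*D standard normals for the Lévy relocation.

    All moves read the positions as they stood at the start of the iteration
    (synchronous update); the hickory squirrel does not move.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, fitness_fn, dim, rng)
    trace_rows: list[dict] = []
    for t in range(1, config.max_iterations + 1):
        assign_roles(pop, config)
        old = pop.positions.copy()
        hickory_idx = pop.indices_of(HICKORY)
        acorn_idx = pop.indices_of(ACORN)
        normal_idx = pop.indices_of(NORMAL)
        # the glide target is the best hickory squirrel
        ht_best = hickory_idx[np.argmin(pop.fitness[hickory_idx])]
        pos_ht = old[ht_best]

        new_positions = old.copy()
        for i in acorn_idx:
            glide = sample_glide(config, rng)
            new_positions[i] = update_acorn_towards_hickory(old[i], pos_ht, glide, config, rng)

        perm = np.asarray(rng.permutation(normal_idx))
        to_acorn = set(perm[: len(normal_idx) // 2].tolist())
        for i in normal_idx:
            if i in to_acorn and len(acorn_idx) > 0:
                j = acorn_idx[int(rng.integers(0, len(acorn_idx)))]
                glide = sample_glide(config, rng)
                new_positions[i] = update_normal_towards_acorn(old[i], old[j], glide, config, rng)
            else:
                glide = sample_glide(config, rng)
                new_positions[i] = update_normal_towards_hickory(old[i], pos_ht, glide, config, rng)

        moved = np.concatenate([acorn_idx, normal_idx])
        try:
            pop.fitness[moved] = _evaluate(fitness_fn, new_positions[moved], f"iteration {t}")
        except ValueError as err:
            raise ValueError(f"iteration {t}: {err}") from err
        pop.positions = new_positions

        winter = False
        if len(acorn_idx) > 0:
            sc = seasonal_constant(new_positions[acorn_idx], new_positions[ht_best])
            smin = season_threshold(t, config.max_iterations, config.season_threshold_scale)
            if float(sc.min()) < smin:
                winter = True
                for i in normal_idx:
                    pop.positions[i] = winter_relocate(config, rng, dim)
                pop.fitness[normal_idx] = _evaluate(
                    fitness_fn, pop.positions[normal_idx], f"iteration {t} (winter)"
                )

        best = int(np.argmin(pop.fitness))
        if pop.fitness[best] < pop.best_fitness:
            pop.best_fitness = float(pop.fitness[best])
            pop.best_position = pop.positions[best].copy()
        pop.iteration = t
        trace_rows.append(
            {
                "iteration": t,
                "best_fitness": pop.best_fitness,
                "mean_fitness": float(pop.fitness.mean()),
                "winter_triggered": winter,
            }
        )
    assign_roles(pop, config)
    trace = pd.DataFrame(
        trace_rows, columns=["iteration", "best_fitness", "mean_fitness", "winter_triggered"]
    )
    return pop, trace


class SquirrelSearch:
    """Object-oriented front end over :func:`run_ssa`.

    Mirrors the ergonomics of scipy optimizers: construct with the
    configuration, call :meth:`minimize` with an objective and a
    dimensionality, get a result object with ``x``, ``fun`` and the
    convergence trace.
    """

    def __init__(self, config: SSAConfig | None = None, **overrides):
        if config is None:
            config = SSAConfig(**overrides)
        elif overrides:
            config = config.replace(**overrides)
        self.config = config

    def minimize(self, fun: Callable[[np.ndarray], float], dim: int):
        from scipy.optimize import OptimizeResult

        n_evals = 0

        def counted(x):
            nonlocal n_evals
            n_evals += 1
            return fun(x)

        pop, trace = run_ssa(self.config, counted, dim)
        return OptimizeResult(
            x=pop.best_position,
            fun=pop.best_fitness,
            nit=self.config.max_iterations,
            nfev=n_evals,
            trace=trace,
            population=pop,
            success=True,
        )
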