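"""Chaos-enhanced accelerated particle swarm optimization (CAPSO).

The accelerated PSO variant drops velocities and personal bests: each
particle is pulled toward the current global best and perturbed by a
decaying random kick,

    x_new = (1 - C2) * x + C2 * g + C1 * (r - 1/2),    r ~ U(0, 1) per dimension

where ``C1 = delta**t`` decays geometrically with the iteration index
``t`` (cognitive factor) and the social factor ``C2`` is produced by the
fully chaotic logistic map ``x -> 4 x (1 - x)`` instead of a pseudo-random
draw.  The exploration kick is centered: a one-sided kick ``C1 * r``
would leave every position >= the incumbent best componentwise once the
swarm has collapsed onto it, freezing half the search directions, so the
uniform draw is shifted to zero mean before it enters the update.  The chaotic orbit is dense in [0, 1] (arcsine invariant density),
so C2 sweeps contraction strengths between 0 and 1 while remaining fully
reproducible from its seed.

A classical inertia-weight PSO (:func:`optimize_standard_pso`) is provided
as an internal comparator with the same result contract.

RNG protocol (relied upon by the hand-unrolled equivalence tests):
``numpy.random.default_rng(rng_seed)`` draws, in order, the initial
positions ``uniform(lower, upper, size=(m, d))`` and then one
``uniform(size=(m, d))`` matrix per iteration whose entries, minus 1/2,
are the kick amplitudes.  The
global best is refreshed synchronously after all particles have moved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ChaosDomainError, ConfigurationError, ContractError, OptimizationError

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizationResult",
    "logistic_step",
    "cognitive_factor",
    "update_position",
    "optimize",
    "optimize_standard_pso",
]

logger = logging.getLogger(__name__)

#: Values from which the r=4 logistic map never escapes into chaos:
#: 0 and 0.75 are fixed points, 0.5 -> 1 -> 0 collapses, 0.25 -> 0.75 locks.
LOGISTIC_DEGENERATE_SEEDS = (0.0, 0.25, 0.5, 0.75, 1.0)


def logistic_step(x: float) -> float:
    """One step of the fully chaotic (r = 4) logistic map, ``4 x (1 - x)``.

    Parameters
    ----------
    x : float
        Current chaos variable, must lie in [0, 1].

    Returns
    -------
    float
        Next chaos variable, guaranteed to lie in [0, 1].
    """
    if not 0.0 <= x <= 1.0:
        raise ChaosDomainError(f"chaos variable must lie in [0, 1], got {x!r}")
    return 4.0 * x * (1.0 - x)


def cognitive_factor(delta: float, t: int) -> float:
    """Geometrically decaying cognitive factor ``C1 = delta**t``, t >= 1."""
    if not 0.0 < delta < 1.0:
        raise ConfigurationError(f"delta must lie strictly in (0, 1), got {delta!r}")
    if t < 1:
        raise ConfigurationError(f"iteration index must be >= 1, got {t!r}")
    return delta**t


@dataclass
class SwarmConfig:
    """Hyperparameters of the CAPSO search.

    Defaults follow the published configuration: 60 particles, 2000
    iterations, 1e-7 objective floor.  ``delta`` (base of C1 = delta**t)
    and ``chaos_seed`` are never stated in the source method and are
    exposed here with logged defaults.
    """

    num_particles: int = 60
    max_iterations: int = 2000
    min_error: float = 1.0e-7
    delta: float = 0.97
    lower_bound: float = -10.0
    upper_bound: float = 10.0
    chaos_seed: float = 0.7
    rng_seed: int = 0
    #: evolve one chaotic C2 per particle instead of a single shared scalar
    chaos_per_particle: bool = False

    def __post_init__(self) -> None:
        if self.num_particles < 2:
            raise ConfigurationError("num_particles must be >= 2")
        if self.max_iterations < 0:
            raise ConfigurationError("max_iterations must be >= 0")
        if self.min_error < 0:
            raise ConfigurationError("min_error must be >= 0")
        if not 0.0 < self.delta < 1.0:
            raise ConfigurationError(f"delta must lie in (0, 1), got {self.delta!r}")
        if not self.lower_bound < self.upper_bound:
            raise ConfigurationError("lower_bound must be strictly below upper_bound")
        if not 0.0 < self.chaos_seed < 1.0 or self.chaos_seed in LOGISTIC_DEGENERATE_SEEDS:
            raise ConfigurationError(
                "chaos_seed must lie in (0, 1) and avoid the logistic map's "
                f"fixed/absorbing values {LOGISTIC_DEGENERATE_SEEDS}, got {self.chaos_seed!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SwarmConfig":
        """Build a config from a flat mapping (YAML/JSON config block)."""
        aliases = {
            "particles": "num_particles",
            "iterations": "max_iterations",
            "iters": "max_iterations",
        }
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, value in mapping.items():
            name = aliases.get(key, key)
            if name not in valid:
                raise ConfigurationError(f"unknown swarm option {key!r}")
            kwargs[name] = value
        return cls(**kwargs)


@dataclass
class SwarmState:
    """Mutable state of a running swarm (exposed for inspection/logging)."""

    positions: np.ndarray
    global_best_position: np.ndarray
    global_best_value: float
    chaos_value: np.ndarray  # scalar array, or per-particle vector
    iteration: int = 0


@dataclass
class OptimizationResult:
    """Outcome of a swarm run."""

    best_position: np.ndarray
    best_value: float
    iterations_run: int
    converged_by_error: bool
    best_value_trace: np.ndarray  # initial best followed by one entry per iteration
    n_evaluations: int = 0
    c1_trace: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    c2_trace: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def update_position(
    x: np.ndarray,
    global_best: np.ndarray,
    c1: float,
    c2: float,
    r: np.ndarray,
    lower_bound: float = -np.inf,
    upper_bound: float = np.inf,
) -> np.ndarray:
    """Accelerated-PSO position update, clamped to the search box.

    Componentwise ``(1 - c2) * x + c2 * global_best + c1 * r`` followed by
    clipping to ``[lower_bound, upper_bound]``.
    """
    x = np.asarray(x, dtype=float)
    global_best = np.asarray(global_best, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != global_best.shape or x.shape != r.shape:
        raise ContractError(
            f"dimension mismatch: x{x.shape}, global_best{global_best.shape}, r{r.shape}"
        )
    new = (1.0 - c2) * x + c2 * global_best + c1 * r
    return np.clip(new, lower_bound, upper_bound)


def _evaluate(
    objective: Callable[[np.ndarray], float],
    batch_objective: Optional[Callable[[np.ndarray], np.ndarray]],
    positions: np.ndarray,
) -> np.ndarray:
    if batch_objective is not None:
        values = np.asarray(batch_objective(positions), dtype=float)
        if values.shape != (positions.shape[0],):
            raise ContractError(
                f"batch objective returned shape {values.shape}, "
                f"expected ({positions.shape[0]},)"
            )
    else:
        values = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise OptimizationError(
            f"objective returned non-finite value {values[bad]!r} "
            f"at position {positions[bad]!r}"
        )
    return values


def optimize(
    objective: Callable[[np.ndarray], float],
    dimension: int,
    config: SwarmConfig,
    batch_objective: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    callback: Optional[Callable[[SwarmState], None]] = None,
) -> OptimizationResult:
    """Minimize ``objective`` over the box with the CAPSO search.

    Parameters
    ----------
    objective : callable
        Maps a d-vector to a finite float.
    dimension : int
        Search-space dimension d.
    config : SwarmConfig
        Hyperparameters; identical configs (both seeds) give bit-identical
        results.
    batch_objective : callable, optional
        Vectorized evaluator mapping an (m, d) position matrix to an
        (m,)-vector of values.  Must agree with ``objective``; when given
        it is used instead, leaving the random stream unchanged.
    callback : callable, optional
        Invoked with the :class:`SwarmState` after every iteration.
    """
    if dimension < 1:
        raise ConfigurationError("dimension must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    m = config.num_particles
    lo, hi = config.lower_bound, config.upper_bound

    positions = rng.uniform(lo, hi, size=(m, dimension))
    values = _evaluate(objective, batch_objective, positions)
    best_idx = int(np.argmin(values))
    best_value = float(values[best_idx])
    best_position = positions[best_idx].copy()

    if config.chaos_per_particle:
        chaos = np.empty(m)
        c = config.chaos_seed
        for i in range(m):
            chaos[i] = c
            c = logistic_step(c)
    else:
        chaos = np.array([config.chaos_seed])

    trace = [best_value]
    c1_trace: list = []
    c2_trace: list = []
    state = SwarmState(positions, best_position, best_value, chaos, 0)
    converged = best_value <= config.min_error
    t = 0
    n_evaluations = m

    while not converged and t < config.max_iterations:
        t += 1
        c1 = cognitive_factor(config.delta, t)
        chaos = np.array([logistic_step(c) for c in chaos])
        c2 = chaos if config.chaos_per_particle else float(chaos[0])
        kick = rng.uniform(size=(m, dimension)) - 0.5

        c2_col = np.reshape(c2, (-1, 1)) if config.chaos_per_particle else c2
        positions = np.clip(
            (1.0 - c2_col) * positions + c2_col * best_position + c1 * kick, lo, hi
        )
        values = _evaluate(objective, batch_objective, positions)
        n_evaluations += m

        idx = int(np.argmin(values))
        if values[idx] < best_value:
            best_value = float(values[idx])
            best_position = positions[idx].copy()

        trace.append(best_value)
        c1_trace.append(c1)
        c2_trace.append(float(np.mean(c2)))
        state = SwarmState(positions, best_position, best_value, chaos, t)
        logger.debug(
            "iter=%d C1=%.6g C2=%s best=%.10g", t, c1,
            np.array2string(np.atleast_1d(np.asarray(c2))[:1], precision=6), best_value,
        )
        if callback is not None:
            callback(state)
        converged = best_value <= config.min_error

    return OptimizationResult(
        best_position=best_position,
        best_value=best_value,
        iterations_run=t,
        converged_by_error=converged,
        best_value_trace=np.asarray(trace),
        n_evaluations=n_evaluations,
        c1_trace=np.asarray(c1_trace),
        c2_trace=np.asarray(c2_trace),
    )


def optimize_standard_pso(
    objective: Callable[[np.ndarray], float],
    dimension: int,
    config: SwarmConfig,
    batch_objective: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    inertia: float = 0.7298,
    accel_personal: float = 1.49618,
    accel_social: float = 1.49618,
) -> OptimizationResult:
    """Classical inertia-weight PSO with personal bests (internal baseline).

    Uses the constriction-equivalent parameter set of Clerc & Kennedy.
    Same stopping rules and result contract as :func:`optimize`.
    """
    if dimension < 1:
        raise ConfigurationError("dimension must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    m = config.num_particles
    lo, hi = config.lower_bound, config.upper_bound
    span = hi - lo

    positions = rng.uniform(lo, hi, size=(m, dimension))
    velocities = np.zeros((m, dimension))
    values = _evaluate(objective, batch_objective, positions)

    pbest_pos = positions.copy()
    pbest_val = values.copy()
    best_idx = int(np.argmin(values))
    best_value = float(values[best_idx])
    best_position = positions[best_idx].copy()

    trace = [best_value]
    converged = best_value <= config.min_error
    t = 0
    n_evaluations = m
    vmax = 0.5 * span

    while not converged and t < config.max_iterations:
        t += 1
        r1 = rng.uniform(size=(m, dimension))
        r2 = rng.uniform(size=(m, dimension))
        velocities = (
            inertia * velocities
            + accel_personal * r1 * (pbest_pos - positions)
            + accel_social * r2 * (best_position - positions)
        )
        np.clip(velocities, -vmax, vmax, out=velocities)
        positions = np.clip(positions + velocities, lo, hi)
        values = _evaluate(objective, batch_objective, positions)
        n_evaluations += m

        improved = values < pbest_val
        pbest_pos[improved] = positions[improved]
        pbest_val[improved] = values[improved]
        idx = int(np.argmin(pbest_val))
        if pbest_val[idx] < best_value:
            best_value = float(pbest_val[idx])
            best_position = pbest_pos[idx].copy()

        trace.append(best_value)
        converged = best_value <= config.min_error

    return OptimizationResult(
        best_position=best_position,
        best_value=best_value,
        iterations_run=t,
        converged_by_error=converged,
        best_value_trace=np.asarray(trace),
        n_evaluations=n_evaluations,
    )
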