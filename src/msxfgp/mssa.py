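"""Multi-strategy improved sparrow search algorithm (MSSA).

A bounded, mixed-integer, derivative-free *maximizer*.  The base sparrow
search algorithm (SSA) evolves a population of candidate positions through
three behavioural roles re-assigned each generation by fitness rank:

* **discoverers** — the fittest fraction, which either contract their
  coordinates multiplicatively (safe foraging) or take a Gaussian step
  (alarm raised);
* **followers** — the remainder, which either track the best discoverer or,
  when badly ranked, jump near the origin scaled by their distance to the
  worst position;
* **vigilantes** — a random subset perturbed around the global best as an
  anti-stagnation measure.

Five strategy refinements are layered on top of the base algorithm:
logistic-chaos population initialization, a linear schedule that shrinks the
discoverer fraction (PD) and grows the vigilante fraction (SD) over the run,
Lévy-flight steps in the vigilante move, an elite archive merged into every
generation, and early stopping on fitness stagnation.

Integer-constrained dimensions stay continuous inside the search dynamics
and are rounded (half away from zero) only when the objective is evaluated
or a position is decoded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "SearchSpace",
    "Population",
    "MSSAConfig",
    "IterationRecord",
    "OptimizeResult",
    "ObjectiveError",
    "round_half_away",
    "logistic_chaos_sequence",
    "init_population_chaotic",
    "adaptive_rates",
    "update_discoverers",
    "update_followers",
    "levy_step",
    "mantegna_sigma",
    "update_vigilantes",
    "elite_merge",
    "check_early_stop",
    "optimize",
]

# Absorbing / periodic points of the fully chaotic (mu=4) logistic map that a
# chaotic initial value must avoid.
_LOGISTIC_FIXED_POINTS = (0.25, 0.5, 0.75)


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer with ties going away from zero.

    ``np.round`` uses banker's rounding (ties to even); the decoding
    convention here requires 6.5 -> 7 and -6.5 -> -7.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box with a per-dimension integrality flag.

    Parameters
    ----------
    lower_bounds, upper_bounds
        Length-``dim`` vectors with ``lower_bounds[j] < upper_bounds[j]``.
    integer_mask
        Boolean vector; ``True`` marks a dimension evaluated at the nearest
        integer (the internal representation stays continuous).
    """

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    integer_mask: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        ub = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        mask = np.atleast_1d(np.asarray(self.integer_mask, dtype=bool))
        if lb.shape != ub.shape or lb.shape != mask.shape or lb.ndim != 1:
            raise ValueError("bounds and integer mask must be 1-D and equal length")
        if lb.size < 1:
            raise ValueError("search space needs at least one dimension")
        if not np.all(lb < ub):
            bad = int(np.argmin(ub - lb))
            raise ValueError(f"lower bound must be < upper bound (dimension {bad})")
        object.__setattr__(self, "lower_bounds", lb)
        object.__setattr__(self, "upper_bounds", ub)
        object.__setattr__(self, "integer_mask", mask)

    @property
    def dim(self) -> int:
        return self.lower_bounds.size

    def clip(self, positions: np.ndarray) -> np.ndarray:
        """Repair out-of-bounds coordinates by hard clipping."""
        return np.clip(positions, self.lower_bounds, self.upper_bounds)

    def round_integers(self, position: np.ndarray) -> np.ndarray:
        """Round integer-masked dimensions (half away from zero) and re-clip."""
        out = np.array(position, dtype=float, copy=True)
        m = self.integer_mask
        if m.any():
            out[..., m] = round_half_away(out[..., m])
        return np.clip(out, self.lower_bounds, self.upper_bounds)


@dataclass
class MSSAConfig:
    """Run-time knobs of the optimizer.

    ``pd_*`` and ``sd_*`` are the endpoints of the linear discoverer /
    vigilante proportion schedules; the discoverer share must not grow and
    the vigilante share must not shrink over the run (global search early,
    local refinement late).  ``alert_threshold`` (ST) gates the two
    discoverer moves.  ``levy_exponent`` is the stability index of the
    Mantegna Lévy step; ``chaos_mu`` drives the logistic initialization map.
    ``early_stop_patience`` defaults to half the iteration budget.
    """

    population_size: int = 50
    max_iterations: int = 50
    alert_threshold: float = 0.8
    pd_start: float = 0.7
    pd_end: float = 0.3
    sd_start: float = 0.1
    sd_end: float = 0.3
    elite_rate: float = 0.1
    levy_exponent: float = 1.5
    early_stop_patience: int | None = None
    chaos_mu: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.5 <= self.alert_threshold <= 1.0:
            raise ValueError("alert_threshold (ST) must lie in [0.5, 1]")
        for name in ("pd_start", "pd_end", "sd_start", "sd_end"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.pd_start < self.pd_end:
            raise ValueError("pd_start must be >= pd_end (discoverers shrink over time)")
        if self.sd_start > self.sd_end:
            raise ValueError("sd_start must be <= sd_end (vigilantes grow over time)")
        if not 0.0 <= self.elite_rate <= 1.0:
            raise ValueError("elite_rate must lie in [0, 1]")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (1, 2]")
        if self.chaos_mu <= 0:
            raise ValueError("chaos_mu must be positive")
        if self.early_stop_patience is not None:
            if self.early_stop_patience < 1 or self.early_stop_patience > self.max_iterations:
                raise ValueError("early_stop_patience must be in [1, max_iterations]")

    @property
    def patience(self) -> int:
        if self.early_stop_patience is not None:
            return self.early_stop_patience
        return max(1, self.max_iterations // 2)


@dataclass
class Population:
    """Positions, fitnesses and the best/worst trackers of one generation."""

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    worst_position: np.ndarray
    worst_fitness: float


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    best_fitness: float
    pd: float
    sd: float
    stagnation_counter: int


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[IterationRecord]
    n_evaluations: int
    stopped_early: bool


class ObjectiveError(RuntimeError):
    """Objective raised inside the optimization loop; carries location context."""

    def __init__(self, iteration: int, particle: int, cause: BaseException):
        super().__init__(
            f"objective failed at iteration {iteration}, particle {particle}: {cause!r}"
        )
        self.iteration = iteration
        self.particle = particle
        self.__cause__ = cause


# ---------------------------------------------------------------------------
# strategy primitives
# ---------------------------------------------------------------------------


def logistic_chaos_sequence(length: int, mu: float, c0: float) -> np.ndarray:
    """Iterate the logistic map ``c <- mu * c * (1 - c)``.

    Returns the iterates ``c1 .. c_length`` (the seed itself is excluded).
    For ``mu <= 4`` and ``c0`` in (0, 1) all iterates stay in [0, 1]; at
    ``mu = 4`` the map is fully chaotic with an arcsine invariant density.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not 0.0 < c0 < 1.0:
        raise ValueError("c0 must lie strictly inside (0, 1)")
    out = np.empty(length, dtype=float)
    c = c0
    for k in range(length):
        c = mu * c * (1.0 - c)
        out[k] = c
    return out


def init_population_chaotic(
    space: SearchSpace,
    n: int,
    rng: np.random.Generator,
    mu: float = 4.0,
    burn_in: int = 10,
) -> np.ndarray:
    """Chaotic population initialization.

    Each matrix element gets an independent logistic-map stream: a uniform
    seed in (0.01, 0.99) steered away from the map's absorbing points, then
    ``burn_in`` iterations so the samples approach the invariant (bimodal)
    density.  Positions are the affine image ``lb + (ub - lb) * C``.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    c = rng.uniform(0.01, 0.99, size=(n, space.dim))
    for p in _LOGISTIC_FIXED_POINTS:
        near = np.abs(c - p) < 1e-9
        if near.any():  # pragma: no cover - measure-zero event, guarded anyway
            c[near] += 1e-6
    for _ in range(burn_in):
        c = mu * c * (1.0 - c)
    return space.lower_bounds + (space.upper_bounds - space.lower_bounds) * c


def adaptive_rates(t: int, config: MSSAConfig) -> tuple[float, float]:
    """Linear discoverer/vigilante proportion schedule at iteration ``t`` (0-based)."""
    if not 0 <= t < config.max_iterations:
        raise ValueError("iteration index out of range")
    m = config.max_iterations
    frac = t / (m - 1) if m > 1 else 0.0
    pd = config.pd_start + (config.pd_end - config.pd_start) * frac
    sd = config.sd_start + (config.sd_end - config.sd_start) * frac
    return pd, sd


def update_discoverers(
    positions: np.ndarray,
    ranks: np.ndarray,
    config: MSSAConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Discoverer move for one generation.

    ``positions`` are the discoverers ordered by fitness; ``ranks`` their
    1-based fitness ranks (1 = best).  One alarm draw R ~ U[0,1] and one
    alpha ~ U(0,1] apply to the whole generation.  Safe regime (R < ST):
    multiplicative contraction ``X * exp(-i / (alpha * M))``.  Alarm regime
    (R >= ST): additive Gaussian step ``X + Q`` with a scalar Q per sparrow
    broadcast over dimensions (Q times the all-ones row).
    """
    positions = np.array(positions, dtype=float, copy=True)
    if positions.shape[0] == 0:
        return positions
    ranks = np.asarray(ranks, dtype=float)
    r_alarm = rng.uniform()
    alpha = 1.0 - rng.random()  # uniform on (0, 1]
    if r_alarm < config.alert_threshold:
        decay = np.exp(-ranks / (alpha * config.max_iterations))
        positions *= decay[:, None]
    else:
        q = rng.standard_normal(positions.shape[0])
        positions += q[:, None]
    return space.clip(positions)


def update_followers(
    positions: np.ndarray,
    ranks: np.ndarray,
    best_discoverer_position: np.ndarray,
    worst_position: np.ndarray,
    n_total: int,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Follower move for one generation.

    ``ranks`` are 1-based fitness ranks within the whole population (the
    worst followers carry the largest ranks).  A follower ranked worse than
    ``n_total / 2`` is starving and relocates to
    ``Q * exp((X_worst - X) / i^2)``; the rest move to the best discoverer
    position X_P plus a signed mean displacement: with A a random +/-1 row,
    the original pseudo-inverse product ``|X - X_P| . A^T (A A^T)^{-1} L``
    collapses to the scalar ``mean(|X - X_P| * A)`` broadcast over
    dimensions.
    """
    positions = np.array(positions, dtype=float, copy=True)
    n_followers = positions.shape[0]
    if n_followers == 0:
        return positions
    ranks = np.asarray(ranks, dtype=float)
    x_p = np.asarray(best_discoverer_position, dtype=float)
    x_w = np.asarray(worst_position, dtype=float)
    for k in range(n_followers):
        i = ranks[k]
        if i > n_total / 2.0:
            q = rng.standard_normal()
            # exponent kept finite: bounded boxes keep it small, but clip defensively
            expo = np.clip((x_w - positions[k]) / (i * i), -50.0, 50.0)
            positions[k] = q * np.exp(expo)
        else:
            a = rng.choice((-1.0, 1.0), size=space.dim)
            step = float(np.mean(np.abs(positions[k] - x_p) * a))
            positions[k] = x_p + step
    return space.clip(positions)


def mantegna_sigma(levy_exponent: float) -> float:
    """Scale ``sigma_u`` of the Mantegna algorithm for stability index beta."""
    b = levy_exponent
    num = _gamma(1.0 + b) * math.sin(math.pi * b / 2.0)
    den = _gamma((1.0 + b) / 2.0) * b * 2.0 ** ((b - 1.0) / 2.0)
    return (num / den) ** (1.0 / b)


def levy_step(
    dim: int, levy_exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed Lévy step ``s = u / |v|^(1/beta)`` (Mantegna method).

    ``u ~ N(0, sigma_u^2)`` with the Gamma-function scale, ``v ~ N(0, 1)``;
    independent per dimension.  A numerically zero ``v`` is resampled so the
    step is always finite.
    """
    if not 1.0 < levy_exponent <= 2.0:
        raise ValueError("levy_exponent must lie in (1, 2]")
    sigma_u = mantegna_sigma(levy_exponent)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.standard_normal(dim)
    while True:
        degenerate = np.abs(v) < 1e-300
        if not degenerate.any():
            break
        v[degenerate] = rng.standard_normal(int(degenerate.sum()))
    return u / np.abs(v) ** (1.0 / levy_exponent)


def update_vigilantes(
    positions: np.ndarray,
    fitness: np.ndarray,
    best_position: np.ndarray,
    best_fitness: float,
    worst_fitness: float,
    config: MSSAConfig,
    space: SearchSpace,
    rng: np.random.Generator,
    eps: float = 1e-8,
) -> np.ndarray:
    """Vigilante move with Lévy flights.

    A sparrow not at the global optimum jumps to
    ``X_best + beta * |X - X_best| * s`` with ``beta ~ N(0,1)`` a scalar step
    control and ``s`` a per-dimension Lévy step.  A sparrow whose fitness
    equals the global best drifts as
    ``X_best + k * (X - X_best) / (|f_i - f_w| + eps)`` with ``k ~ U[-1,1]``.
    """
    positions = np.array(positions, dtype=float, copy=True)
    if positions.shape[0] == 0:
        return positions
    fitness = np.asarray(fitness, dtype=float)
    x_best = np.asarray(best_position, dtype=float)
    for k in range(positions.shape[0]):
        if fitness[k] != best_fitness:
            beta_ctrl = rng.standard_normal()
            s = levy_step(space.dim, config.levy_exponent, rng)
            positions[k] = x_best + beta_ctrl * np.abs(positions[k] - x_best) * s
        else:
            k_rand = rng.uniform(-1.0, 1.0)
            denom = abs(fitness[k] - worst_fitness) + eps
            positions[k] = x_best + k_rand * (positions[k] - x_best) / denom
    return space.clip(positions)


def _rank_order(fitness: np.ndarray) -> np.ndarray:
    """Indices sorted by fitness descending, ties broken by particle index."""
    idx = np.arange(fitness.size)
    return np.lexsort((idx, -fitness))


def elite_merge(
    positions: np.ndarray,
    fitness: np.ndarray,
    elite_positions: np.ndarray,
    elite_fitness: np.ndarray,
    n_keep: int,
    elite_size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Merge the elite archive into the generation and truncate.

    Returns ``(positions, fitness, new_elite_positions, new_elite_fitness)``
    where the population is the ``n_keep`` fittest of the merged set and the
    archive the ``elite_size`` fittest.  With an empty archive and
    ``elite_size == 0`` the generation passes through untouched.
    """
    if elite_size == 0 and elite_fitness.size == 0:
        return positions, fitness, elite_positions, elite_fitness
    merged_pos = np.vstack([positions, elite_positions])
    merged_fit = np.concatenate([fitness, elite_fitness])
    order = _rank_order(merged_fit)
    keep = order[:n_keep]
    arch = order[:elite_size]
    return (
        merged_pos[keep],
        merged_fit[keep],
        merged_pos[arch].copy(),
        merged_fit[arch].copy(),
    )


def check_early_stop(stagnation_counter: int, patience: int) -> bool:
    """True once the best fitness has failed to improve ``patience`` times."""
    if stagnation_counter < 0 or patience < 0:
        raise ValueError("counters must be non-negative")
    return stagnation_counter >= patience


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: MSSAConfig,
) -> OptimizeResult:
    """Maximize ``objective`` over ``space`` with the full MSSA loop.

    The objective receives positions with integer-masked dimensions already
    rounded.  Per iteration: compute the PD/SD schedule, rank the
    population, move discoverers then followers then vigilantes, clip,
    evaluate, merge the elite archive, update the best/worst trackers and
    the stagnation counter, and stop early once the counter reaches the
    patience.  The returned best fitness is the maximum over every
    evaluation performed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    m_iter = config.max_iterations
    patience = config.patience
    elite_size = int(math.floor(n * config.elite_rate))

    def evaluate(pos_matrix: np.ndarray, iteration: int) -> np.ndarray:
        out = np.empty(pos_matrix.shape[0], dtype=float)
        for i in range(pos_matrix.shape[0]):
            try:
                out[i] = float(objective(space.round_integers(pos_matrix[i])))
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise ObjectiveError(iteration, i, exc) from exc
        return out

    positions = init_population_chaotic(space, n, rng, mu=config.chaos_mu)
    fitness = evaluate(positions, -1)
    n_evaluations = n

    best_idx = int(_rank_order(fitness)[0])
    best_position = positions[best_idx].copy()
    best_fitness = float(fitness[best_idx])

    elite_pos = np.empty((0, space.dim))
    elite_fit = np.empty(0)

    history: list[IterationRecord] = []
    stagnation = 0
    stopped_early = False

    for t in range(m_iter):
        pd_t, sd_t = adaptive_rates(t, config)
        order = _rank_order(fitness)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)

        n_disc = min(n, int(math.ceil(pd_t * n)))
        disc = order[:n_disc]
        foll = order[n_disc:]
        worst_position = positions[order[-1]].copy()
        worst_fitness = float(fitness[order[-1]])

        positions[disc] = update_discoverers(
            positions[disc], ranks[disc], config, space, rng
        )
        x_p = positions[disc[0]].copy()  # best discoverer, post-move
        if foll.size:
            positions[foll] = update_followers(
                positions[foll], ranks[foll], x_p, worst_position, n, space, rng
            )

        n_vig = min(n, int(math.ceil(sd_t * n)))
        vig = rng.choice(n, size=n_vig, replace=False)
        positions[vig] = update_vigilantes(
            positions[vig],
            fitness[vig],
            best_position,
            best_fitness,
            worst_fitness,
            config,
            space,
            rng,
        )

        positions = space.clip(positions)
        fitness = evaluate(positions, t)
        n_evaluations += n

        positions, fitness, elite_pos, elite_fit = elite_merge(
            positions, fitness, elite_pos, elite_fit, n, elite_size
        )

        gen_best = int(_rank_order(fitness)[0])
        if fitness[gen_best] > best_fitness:
            best_fitness = float(fitness[gen_best])
            best_position = positions[gen_best].copy()
            stagnation = 0
        else:
            stagnation += 1

        history.append(
            IterationRecord(
                iteration=t,
                best_fitness=best_fitness,
                pd=pd_t,
                sd=sd_t,
                stagnation_counter=stagnation,
            )
        )
        if check_early_stop(stagnation, patience):
            stopped_early = True
            break

    return OptimizeResult(
        best_position=best_position,
        best_fitness=best_fitness,
        history=history,
        n_evaluations=n_evaluations,
        stopped_early=stopped_early,
    )
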