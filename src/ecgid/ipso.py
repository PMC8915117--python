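"""Improved particle swarm optimisation over SVM hyperparameters (c, g).

The swarm searches the rectangle c in [4, 2048] x g in [1/16, 8] for the
penalty/kernel pair maximising cross-validated identification accuracy.
Three modifications distinguish this from plain PSO:

* the inertia weight decays linearly from 0.9 to 0.4 over the run, trading
  early exploration for late exploitation;
* both learning factors decay linearly from 2 to 0.5, shrinking the step
  size of the personal/social attraction over time;
* before each fitness evaluation a particle may mutate: with a small
  probability one of its two coordinates is redrawn uniformly from that
  coordinate's bounds, guarding against premature convergence to a local
  optimum.

Velocities are clamped component-wise to Vmax and positions clipped to the
search box.  All randomness flows from one seeded generator, so runs are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Particle",
    "SwarmConfig",
    "SwarmState",
    "inertia_at",
    "learning_factor_at",
    "mutate",
    "update_particle",
    "optimize",
]

Position = np.ndarray  # (c, g)


@dataclass
class Particle:
    """Position/velocity in (c, g) space plus the personal best."""

    position: Position
    velocity: Position
    best_position: Position
    best_fitness: float


@dataclass(frozen=True)
class SwarmConfig:
    """Schedule constants and search box.

    Defaults are the reference configuration: 20 particles, 50 iterations,
    inertia 0.9 -> 0.4, learning factors 2 -> 0.5, c in [2^2, 2^11],
    g in [2^-4, 2^3], one particle seeded at (c, g) = (10, 2).
    """

    n_particles: int = 20
    max_iter: int = 50
    omega_start: float = 0.9
    omega_end: float = 0.4
    c_max: float = 2.0
    c_min: float = 0.5
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 2048.0), (0.0625, 8.0))
    vmax_fraction: float = 0.2  # Vmax per dimension as a fraction of its span
    mutation_prob: float = 0.1
    init_position: tuple[float, float] | None = (10.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.omega_start > self.omega_end > 0):
            raise ValueError("need omega_start > omega_end > 0")
        if not (self.c_max > self.c_min > 0):
            raise ValueError("need c_max > c_min > 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy lo < hi")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.n_particles < 1 or self.max_iter < 1:
            raise ValueError("n_particles and max_iter must be >= 1")

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def vmax(self) -> np.ndarray:
        return self.vmax_fraction * (self.hi - self.lo)


@dataclass
class SwarmState:
    """Iteration counter, particles, global best and fitness trace."""

    iteration: int
    particles: list[Particle]
    best_position: Position
    best_fitness: float
    history: list[float] = field(default_factory=list)


def inertia_at(iteration: int, max_iter: int, omega_start: float = 0.9, omega_end: float = 0.4) -> float:
    """Linearly decaying inertia weight: omega_start at 0, omega_end at the end."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration outside 0..max_iter")
    return (omega_start - omega_end) * (max_iter - iteration) / max_iter + omega_end


def learning_factor_at(iteration: int, max_iter: int, c_max: float = 2.0, c_min: float = 0.5) -> float:
    """Linearly decaying learning factor: c_max at 0, c_min at the end."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration outside 0..max_iter")
    return c_max + (c_min - c_max) * (iteration / max_iter)


def mutate(bounds: tuple[float, float], rng: np.random.Generator) -> float:
    """Redraw a parameter uniformly on its bounds: (hi - lo) * u + lo."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    return float((hi - lo) * rng.uniform() + lo)


def update_particle(
    particle: Particle,
    pbest: Position,
    omega: float,
    c1: float,
    c2: float,
    vmax: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """One velocity/position update with clamping and box clipping.

    v <- omega*v + c1*u1*(ibest - x) + c2*u2*(pbest - x), |v_d| <= vmax_d;
    x <- clip(x + v).
    """
    u1, u2 = rng.uniform(size=2)
    v = (
        omega * particle.velocity
        + c1 * u1 * (particle.best_position - particle.position)
        + c2 * u2 * (pbest - particle.position)
    )
    v = np.clip(v, -vmax, vmax)
    particle.velocity = v
    particle.position = np.clip(particle.position + v, lo, hi)


def optimize(
    fitness: Callable[[float, float], float],
    config: SwarmConfig | None = None,
    callback: Callable[[SwarmState], None] | None = None,
) -> tuple[float, float, float, list[float]]:
    """Run the swarm; returns (best c, best g, best fitness, history).

    Each iteration: adaptive mutation (probability per particle; the mutated
    coordinate chosen at random is redrawn on its bounds) -> fitness
    evaluation -> personal/global best updates -> scheduled velocity/position
    update.  ``history`` holds the global best after every iteration and is
    monotone non-decreasing.
    """
    config = config or SwarmConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi, vmax = config.lo, config.hi, config.vmax

    particles: list[Particle] = []
    for i in range(config.n_particles):
        if i == 0 and config.init_position is not None:
            x = np.clip(np.asarray(config.init_position, dtype=float), lo, hi)
        else:
            x = rng.uniform(lo, hi)
        particles.append(
            Particle(
                position=x,
                velocity=np.zeros_like(x),
                best_position=x.copy(),
                best_fitness=-np.inf,
            )
        )

    best_position = particles[0].position.copy()
    best_fitness = -np.inf
    history: list[float] = []
    state = SwarmState(0, particles, best_position, best_fitness, history)

    for it in range(config.max_iter):
        omega = inertia_at(it, config.max_iter, config.omega_start, config.omega_end)
        c_t = learning_factor_at(it, config.max_iter, config.c_max, config.c_min)
        for p in particles:
            # adaptive mutation before the fitness evaluation
            if rng.uniform() < config.mutation_prob:
                dim = int(rng.integers(2))
                p.position = p.position.copy()
                p.position[dim] = mutate(config.bounds[dim], rng)
            f = float(fitness(p.position[0], p.position[1]))
            if not np.isfinite(f):
                raise FloatingPointError(
                    f"non-finite fitness at position {tuple(p.position)}"
                )
            if f > p.best_fitness:
                p.best_fitness = f
                p.best_position = p.position.copy()
            if f > best_fitness:
                best_fitness = f
                best_position = p.position.copy()
        for p in particles:
            update_particle(p, best_position, omega, c_t, c_t, vmax, lo, hi, rng)
        history.append(best_fitness)
        state.iteration = it + 1
        state.best_position = best_position
        state.best_fitness = best_fitness
        if callback is not None:
            callback(state)

    return float(best_position[0]), float(best_position[1]), float(best_fitness), history
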