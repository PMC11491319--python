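"""Colliding Bodies Optimization (CBO), a population metaheuristic.

Each candidate solution is a "body" with a mass inversely proportional to
its fitness. Per iteration the population is sorted by fitness and split in
half: the better half is stationary (zero pre-collision velocity), the worse
half moves toward its stationary partner with velocity v_i = x_partner - x_i.
One-dimensional collision mechanics with coefficient of restitution eps give
post-collision velocities

    moving:     v'_i = (m_i - eps * m_p) * v_i / (m_i + m_p)
    stationary: v'_p = (m_i + eps * m_i) * v_i / (m_i + m_p)

(p the stationary partner of moving body i), and both bodies step from the
collision site scaled by a fresh uniform [-1, 1] vector per body. The
algorithm is memoryless — the best-so-far is tracked for reporting only.

Masses require positive fitness; :func:`optimize` positivizes a raw
objective either by shifting with a declared finite lower bound or by an
exponentially rescaled rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

EpsSchedule = Callable[[int, int], float]


def linear_epsilon(iteration: int, max_iters: int) -> float:
    """Default restitution schedule: eps(t) = 1 - t/max_iters (elastic -> plastic)."""
    return 1.0 - iteration / max_iters


@dataclass(frozen=True)
class CBOConfig:
    n: int = 30
    dims: int = 2
    bounds: tuple[tuple[float, float], ...] = ((-5.0, 5.0), (-5.0, 5.0))
    max_iters: int = 200
    epsilon_schedule: EpsSchedule = field(default=linear_epsilon)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 4 or self.n % 2 != 0:
            raise ValueError(f"population size must be even and >= 4, got {self.n}")
        if len(self.bounds) != self.dims:
            raise ValueError("bounds must give (lo, hi) per dimension")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class CBOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # per-iteration best-so-far raw objective


def initialize(config: CBOConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform positions in the bounded box, one row per body."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng.uniform(config.lower, config.upper, size=(config.n, config.dims))


def compute_masses(fitnesses: Sequence[float]) -> np.ndarray:
    """m_k = (1/fit_k) / sum_i (1/fit_i); requires all fitnesses > 0."""
    fit = np.asarray(fitnesses, dtype=float)
    if np.any(fit <= 0) or not np.all(np.isfinite(fit)):
        raise ValueError("fitness values must be positive and finite; positivize the objective")
    inv = 1.0 / fit
    return inv / inv.sum()


def collide(
    positions: np.ndarray,
    masses: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    fitnesses: np.ndarray | None = None,
) -> np.ndarray:
    """One collision step on a population sorted ascending by fitness.

    Returns new positions, clipped to bounds. If ``fitnesses`` is given the
    ascending-sort precondition is checked.
    """
    n = positions.shape[0]
    if n % 2 != 0:
        raise ValueError("population size must be even")
    if fitnesses is not None and np.any(np.diff(fitnesses) < 0):
        raise ValueError("population must be sorted ascending by fitness before collide")
    half = n // 2
    x_s, x_m = positions[:half], positions[half:]
    m_s, m_m = masses[:half, None], masses[half:, None]

    v = x_s - x_m  # moving body's pre-collision velocity toward its partner
    denom = m_m + m_s
    v_moving = (m_m - epsilon * m_s) * v / denom
    v_stationary = (m_m + epsilon * m_m) * v / denom

    rand = rng.uniform(-1.0, 1.0, size=positions.shape)
    new = np.empty_like(positions)
    new[:half] = x_s + rand[:half] * v_stationary
    new[half:] = x_s + rand[half:] * v_moving  # moving body restarts at collision site
    return np.clip(new, lower, upper)


def _positivize(raw: np.ndarray, lower_bound: float | None) -> np.ndarray:
    if lower_bound is not None:
        return raw - lower_bound + 1.0
    if np.all(raw > 0):
        return raw
    # rank-based fallback: positive, order-preserving
    order = np.argsort(np.argsort(raw))
    return np.exp(order / max(len(raw) - 1, 1))


def optimize(
    objective: Callable[[np.ndarray], float],
    config: CBOConfig,
    lower_bound: float | None = None,
) -> CBOResult:
    """Run CBO on a scalar objective over a bounded box (minimization).

    ``lower_bound``, when finite and known, shifts raw objective values to
    the positive fitness Eq-style masses require; otherwise positive raw
    values are used directly, falling back to exp-rescaled ranks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = initialize(config, rng)
    lo, hi = config.lower, config.upper

    best_position: np.ndarray | None = None
    best_raw = np.inf
    history = np.empty(config.max_iters)

    for t in range(config.max_iters):
        raw = np.array([objective(x) for x in positions], dtype=float)
        if not np.all(np.isfinite(raw)):
            bad = positions[~np.isfinite(raw)][0]
            raise FloatingPointError(f"objective returned non-finite value at {bad}")
        i_best = int(np.argmin(raw))
        if raw[i_best] < best_raw:
            best_raw = float(raw[i_best])
            best_position = positions[i_best].copy()
        history[t] = best_raw

        order = np.argsort(raw, kind="stable")
        positions, raw = positions[order], raw[order]
        masses = compute_masses(_positivize(raw, lower_bound))
        epsilon = float(config.epsilon_schedule(t, config.max_iters))
        positions = collide(positions, masses, epsilon, rng, lo, hi, fitnesses=raw)

    assert best_position is not None
    return CBOResult(best_position=best_position, best_fitness=best_raw, history=history)


def history_to_csv(result: CBOResult, path: str) -> None:
    """Export the convergence history as (iteration, best_fitness) CSV."""
    import pandas as pd

    pd.DataFrame(
        {"iteration": np.arange(len(result.history)), "best_fitness": result.history}
    ).to_csv(path, index=False)
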