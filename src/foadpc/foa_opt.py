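"""Fruit-fly optimization (FOA) with random step size over (d_c, k).

Classic FOA alternates a smell-based search — each fly proposes a random
move around the swarm anchor and its proposal is scored by the smell
concentration (fitness) function — and a visual search — the swarm
relocates to the best fly's position.  Here the swarm lives directly in
the two-dimensional decision space: the first coordinate carries the
cut-off distance d_c, the second the center count k, and each smell step
adds an independent uniform random step from [step_low, step_high]
(default [-5, 5]) to each coordinate.  Positions decode to valid
parameters by clamping into the search box ([1,10] x [2,40]) and
rounding k half-up to an integer.

The anchor update is elitist: the swarm only relocates when the
generation's best proposal improves on the best smell found so far, so
the convergence trace is non-decreasing.  All randomness flows from the
configured seed; a fixed seed reproduces the run bit for bit.

The classic formulation scores a fly by the reciprocal of its distance
to the origin, S = 1/sqrt(X^2 + Y^2); that transform is exposed as
:func:`smell_concentration` for reference but plays no role in the
direct decision-space search used here (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dpc_core import DC_BOUNDS, K_BOUNDS, DPCParams

logger = logging.getLogger(__name__)

#: Per-variable (low, high) search box: d_c then k.
DEFAULT_BOUNDS: tuple[tuple[float, float], tuple[float, float]] = (
    DC_BOUNDS,
    (float(K_BOUNDS[0]), float(K_BOUNDS[1])),
)


class ConfigError(ValueError):
    """Invalid optimizer or pipeline configuration."""


@dataclass(frozen=True)
class FOAConfig:
    """Swarm settings; defaults follow the method's reference setup
    (population 10, 10 generations, uniform random steps in [-5, 5])."""

    sizepop: int = 10
    maxgen: int = 10
    step_low: float = -5.0
    step_high: float = 5.0
    seed: int | None = None
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.sizepop < 1 or self.maxgen < 1:
            raise ConfigError("sizepop and maxgen must be positive")
        if not self.step_low < self.step_high:
            raise ConfigError("step_low must be strictly below step_high")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigError(f"degenerate bounds ({lo}, {hi})")


@dataclass
class FlySwarm:
    """Mutable optimizer state: the anchor, current proposals and the
    elitist best-so-far record."""

    axis: np.ndarray  # anchor, shape (2,)
    positions: np.ndarray | None = None  # (sizepop, 2) proposals
    smell: np.ndarray | None = None  # (sizepop,) fitness values
    best_smell: float = -math.inf
    best_params: DPCParams | None = None
    trace: list[float] = field(default_factory=list)


def smell_concentration(x: float, y: float) -> tuple[float, float]:
    """Classic FOA odor transform: distance to the origin and its
    reciprocal, (Dist, S) = (sqrt(x^2+y^2), 1/Dist)."""
    dist = math.hypot(x, y)
    return dist, (math.inf if dist == 0.0 else 1.0 / dist)


def decode(
    position: np.ndarray,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
) -> DPCParams:
    """Map a swarm position to valid parameters: clamp the first
    coordinate into the d_c range and the second, rounded half-up, into
    the k range."""
    x, y = float(position[0]), float(position[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("position must be finite")
    (lo_dc, hi_dc), (lo_k, hi_k) = bounds
    d_c = min(max(x, lo_dc), hi_dc)
    k = int(math.floor(min(max(y, lo_k), hi_k) + 0.5))
    k = min(max(k, int(lo_k)), int(hi_k))
    return DPCParams(d_c=d_c, k=k)


def init_swarm(config: FOAConfig, rng: np.random.Generator) -> FlySwarm:
    """Place the anchor uniformly at random inside the search box."""
    lows = np.array([b[0] for b in config.bounds])
    highs = np.array([b[1] for b in config.bounds])
    return FlySwarm(axis=rng.uniform(lows, highs))


def smell_step(
    swarm: FlySwarm, config: FOAConfig, rng: np.random.Generator
) -> np.ndarray:
    """One random proposal per fly: anchor plus an independent uniform
    step in [step_low, step_high] per coordinate."""
    steps = rng.uniform(config.step_low, config.step_high,
                        size=(config.sizepop, 2))
    return swarm.axis + steps


def select_best(smells: np.ndarray) -> tuple[float, int]:
    """Maximum smell and its first index (ties go to the lowest index)."""
    smells = np.asarray(smells, dtype=float)
    if smells.size == 0:
        raise ValueError("no smells to select from")
    if not np.all(np.isfinite(smells)):
        raise ValueError("fitness returned a non-finite value")
    idx = int(np.argmax(smells))
    return float(smells[idx]), idx


def visual_step(
    swarm: FlySwarm,
    positions: np.ndarray,
    smells: np.ndarray,
    decoded: list[DPCParams],
) -> FlySwarm:
    """Elitist relocation: the anchor moves to the generation's best fly
    only if that fly improves on the best smell so far; the trace is
    extended either way."""
    best, idx = select_best(smells)
    if best > swarm.best_smell:
        swarm.axis = positions[idx].copy()
        swarm.best_smell = best
        swarm.best_params = decoded[idx]
    swarm.trace.append(swarm.best_smell)
    return swarm


@dataclass(frozen=True)
class FOAResult:
    best_params: DPCParams
    best_smell: float
    trace: np.ndarray
    evaluations: int


def optimize(fitness, config: FOAConfig | None = None) -> FOAResult:
    """Run the swarm for maxgen generations and return the elitist
    optimum over all sizepop * maxgen evaluated candidates."""
    config = config or FOAConfig()
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(config, rng)
    for gen in range(config.maxgen):
        positions = smell_step(swarm, config, rng)
        decoded = [decode(p, config.bounds) for p in positions]
        smells = np.array([float(fitness(p)) for p in decoded])
        visual_step(swarm, positions, smells, decoded)
        logger.info(
            "foa gen=%d best_smell=%.6f d_c=%.3f k=%d",
            gen + 1, swarm.best_smell,
            swarm.best_params.d_c, swarm.best_params.k,
        )
    return FOAResult(
        best_params=swarm.best_params,
        best_smell=swarm.best_smell,
        trace=np.array(swarm.trace),
        evaluations=config.sizepop * config.maxgen,
    )
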