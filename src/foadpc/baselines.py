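"""Comparison methods: exhaustive grid search, weighted 1-D k-means and
a plain real-coded genetic algorithm over (d_c, k).

The grid search enumerates the whole effective parameter lattice
d_c in {1..10} x k in {2..40} (390 cells; integer d_c values cover every
equivalence class of the continuous range, since only ceil(d_c) affects
the clustering) and is the deterministic upper bound every stochastic
optimizer is measured against.

k-means quantizes the gray axis directly: Lloyd's algorithm on the
present gray levels weighted by their pixel counts, with seeded
k-means++ initialization (scikit-learn).

The GA stands in for a genetic-algorithm-tuned DPC at its published
budget (population 10, 20 generations): tournament selection of size 2,
BLX-0.5 blend crossover at rate 0.9, per-gene mutation at rate 0.1
(uniform reset, half the time snapped to a box boundary), elitism of 1,
sharing the decode/clamp of the fruit-fly optimizer.  Blend crossover
and boundary mutation matter here: a maximum-entropy objective leans on
the upper k bound (H <= log2 k), and purely interpolative operators
cannot reach a boundary optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import dpc_core, fitness as fit_mod
from .dpc_core import DC_BOUNDS, K_BOUNDS, DPCParams
from .foa_opt import DEFAULT_BOUNDS, ConfigError, decode
from .gray_io import GrayHistogram

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridResult:
    """Fitness over the full (d_c, k) lattice plus its argmax.

    ``table`` is indexed by d_c (rows 1..10) with one column per k
    (2..40); ties at the maximum resolve to the lexicographically
    smallest (d_c, k)."""

    table: pd.DataFrame
    best_params: DPCParams
    best_fitness: float
    trace: np.ndarray  # running best in evaluation order


def grid_search(hist: GrayHistogram, fitness=None) -> GridResult:
    """Evaluate the DPC-entropy objective at every lattice cell."""
    if fitness is None:
        fitness = fit_mod.make_entropy_fitness(hist)
    dcs = range(int(DC_BOUNDS[0]), int(DC_BOUNDS[1]) + 1)
    ks = range(K_BOUNDS[0], K_BOUNDS[1] + 1)
    table = pd.DataFrame(index=list(dcs), columns=list(ks), dtype=float)
    table.index.name = "d_c"
    table.columns.name = "k"
    best, best_params, running = -np.inf, None, []
    for d_c in dcs:
        for k in ks:
            value = float(fitness(DPCParams(float(d_c), k)))
            table.loc[d_c, k] = value
            if value > best:
                best, best_params = value, DPCParams(float(d_c), k)
            running.append(best)
    return GridResult(table=table, best_params=best_params,
                      best_fitness=best, trace=np.array(running))


def kmeans_gray(hist: GrayHistogram, k: int, seed: int | None = None) -> dict[int, int]:
    """Weighted 1-D k-means of the present gray levels.

    Returns the level -> cluster map with clusters relabeled in
    ascending-centroid order for determinism.
    """
    levels = hist.levels
    if not 2 <= k <= len(levels):
        raise ValueError(f"k={k} must be in [2, #levels={len(levels)}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed)
    raw = km.fit_predict(levels.reshape(-1, 1).astype(float),
                         sample_weight=hist.counts[levels].astype(float))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    return {int(g): int(relabel[c]) for g, c in zip(levels, raw)}


@dataclass(frozen=True)
class GAResult:
    best_params: DPCParams
    best_smell: float
    trace: np.ndarray
    evaluations: int


def ga_optimize(
    fitness,
    pop: int = 10,
    gens: int = 20,
    seed: int | None = None,
    bounds=DEFAULT_BOUNDS,
    crossover_rate: float = 0.9,
    mutation_rate: float = 0.1,
    blx_alpha: float = 0.5,
) -> GAResult:
    """Real-coded GA over the (d_c, k) box, elitism of 1.

    Each generation evaluates every individual (pop * gens evaluations
    total) and the elitist trace is non-decreasing.  Children are
    clipped to the box.
    """
    if pop < 2 or gens < 1:
        raise ConfigError("pop must be >= 2 and gens >= 1")
    rng = np.random.default_rng(seed)
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    population = rng.uniform(lows, highs, size=(pop, 2))
    best_smell, best_params, best_pos = -np.inf, None, None
    trace = []
    for gen in range(gens):
        decoded = [decode(p, bounds) for p in population]
        smells = np.array([float(fitness(p)) for p in decoded])
        if not np.all(np.isfinite(smells)):
            raise ValueError("fitness returned a non-finite value")
        idx = int(np.argmax(smells))
        if smells[idx] > best_smell:
            best_smell = float(smells[idx])
            best_params = decoded[idx]
            best_pos = population[idx].copy()
        trace.append(best_smell)
        logger.info("ga gen=%d best_smell=%.6f", gen + 1, best_smell)
        if gen == gens - 1:
            break
        nxt = np.empty_like(population)
        nxt[0] = best_pos  # elitism
        for i in range(1, pop):
            p1 = _tournament(population, smells, rng)
            p2 = _tournament(population, smells, rng)
            if rng.random() < crossover_rate:
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                spread = hi - lo
                child = rng.uniform(lo - blx_alpha * spread,
                                    hi + blx_alpha * spread)
            else:
                child = p1.copy()
            for j in range(2):
                if rng.random() < mutation_rate:
                    u = rng.random()
                    if u < 0.25:
                        child[j] = lows[j]
                    elif u < 0.5:
                        child[j] = highs[j]
                    else:
                        child[j] = rng.uniform(lows[j], highs[j])
            nxt[i] = np.clip(child, lows, highs)
        population = nxt
    return GAResult(best_params=best_params, best_smell=best_smell,
                    trace=np.array(trace), evaluations=pop * gens)


def _tournament(population: np.ndarray, smells: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    i, j = rng.integers(0, len(population), size=2)
    return population[i] if smells[i] >= smells[j] else population[j]
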