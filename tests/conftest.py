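from dataclasses import dataclass

import numpy as np
import pytest

import foadpc as f


def make_hist(counts: dict[int, int]) -> f.GrayHistogram:
    """Histogram from a {gray: count} dict."""
    arr = np.zeros(256, dtype=np.int64)
    for g, c in counts.items():
        arr[g] = c
    return f.GrayHistogram(arr)


@pytest.fixture
def four_level_hist():
    """The worked 4-level example: two close pairs far apart."""
    return make_hist({10: 5, 11: 3, 50: 4, 51: 6})


@dataclass
class SwarmRuns:
    """Optimizer runs on one phantom, shared across acceptance checks."""

    spec: f.PhantomSpec
    grid: f.GridResult
    foa: list[f.FOAResult]
    ga: list[f.GAResult]


N_SEEDS = 20


@pytest.fixture(scope="session")
def suite_runs() -> list[SwarmRuns]:
    """Grid search plus 20 seeded FOA and GA runs on each of the five
    standard phantoms (fitness evaluations memoized per phantom)."""
    out = []
    for spec in f.default_suite(0):
        img, _ = f.generate(spec)
        hist = f.histogram(img)
        fitness = f.make_entropy_fitness(hist)
        grid = f.grid_search(hist, fitness)
        foa = [f.optimize(fitness, f.FOAConfig(seed=s)) for s in range(N_SEEDS)]
        ga = [f.ga_optimize(fitness, seed=s) for s in range(N_SEEDS)]
        out.append(SwarmRuns(spec=spec, grid=grid, foa=foa, ga=ga))
    return out
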