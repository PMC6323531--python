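"""Density-peaks clustering (DPC) of the frequency-weighted gray levels.

The data points are the image's pixels; the distance between two pixels is
the absolute difference of their gray levels.  Because pixels at the same
level are indistinguishable, everything reduces to the present gray levels
weighted by their histogram counts:

* local density  rho(g)  = number of pixels whose level g' satisfies
  |g - g'| < d_c (the pixel's own level included);
* relative distance  delta(g) = distance to the nearest level of strictly
  higher density rank; for the top-ranked level, the maximum distance to
  any other level (the original-DPC convention);
* gamma(g) = rho(g) * delta(g) ranks candidate cluster centers; the k
  largest become centers and every remaining level, visited in decreasing
  density rank, inherits the cluster of its nearest higher-ranked level.

Density ties are totally ordered by (rho desc, counts desc, gray asc),
which makes every result deterministic.  Note that because gray distances
are integers and the density test is the strict inequality |g-g'| < d_c,
only ceil(d_c) matters: all d_c in (n-1, n] give identical clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gray_io import GrayHistogram

#: Search bounds for the cut-off distance d_c.
DC_BOUNDS = (1.0, 10.0)
#: Search bounds for the number of cluster centers k.
K_BOUNDS = (2, 40)


@dataclass(frozen=True)
class DPCParams:
    """Decision variables of the clustering: cut-off distance and center
    count, restricted to d_c in [1, 10] and k in [2, 40]."""

    d_c: float
    k: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_c):
            raise ValueError("d_c must be finite")
        if not DC_BOUNDS[0] <= self.d_c <= DC_BOUNDS[1]:
            raise ValueError(f"d_c={self.d_c} outside {DC_BOUNDS}")
        if int(self.k) != self.k:
            raise ValueError("k must be an integer")
        if not K_BOUNDS[0] <= self.k <= K_BOUNDS[1]:
            raise ValueError(f"k={self.k} outside {K_BOUNDS}")


@dataclass(frozen=True)
class DensityProfile:
    """Per-present-level DPC quantities.

    ``levels`` is ascending; ``rho``, ``delta``, ``gamma``, ``counts`` are
    aligned with it.  ``rank`` holds the position of each level in the
    total density order (0 = densest); ``nn_higher`` holds, for each
    level, the gray level of its nearest strictly-higher-ranked level
    (-1 for the top-ranked level, which has none).
    """

    levels: np.ndarray
    counts: np.ndarray
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    nn_higher: np.ndarray
    rank: np.ndarray

    @property
    def rank_order(self) -> np.ndarray:
        """Indices into ``levels`` from densest to least dense."""
        return np.argsort(self.rank)


@dataclass(frozen=True)
class DPCModel:
    """A fitted clustering: centers and the gray-level -> cluster map."""

    params: DPCParams
    profile: DensityProfile
    centers: np.ndarray  # center gray levels, in descending-gamma order
    level_label: dict[int, int]

    @property
    def effective_k(self) -> int:
        """Requested k clamped to the number of present levels."""
        return len(self.centers)


def chi(x: float) -> int:
    """Neighborhood indicator: 1 if x < 0 else 0."""
    return 1 if x < 0 else 0


def compute_density(hist: GrayHistogram, d_c: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted local density per present level.

    Returns ``(levels, rho)`` where ``rho[i]`` counts every pixel whose
    gray level lies strictly within d_c of ``levels[i]`` (self included).
    """
    if not DC_BOUNDS[0] <= d_c <= DC_BOUNDS[1]:
        raise ValueError(f"d_c={d_c} outside {DC_BOUNDS}")
    levels = hist.levels
    counts = hist.counts[levels]
    dist = np.abs(levels[:, None] - levels[None, :])
    rho = (dist < d_c) @ counts
    return levels, rho.astype(np.int64)


def _rank_order(levels: np.ndarray, rho: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Total density order: rho desc, counts desc, gray asc."""
    return np.lexsort((levels, -counts, -rho))


def compute_delta(
    levels: np.ndarray, rho: np.ndarray, counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative distance and nearest-denser neighbor per level.

    Levels are totally ordered by (rho desc, counts desc, gray asc).  A
    non-top level's delta is its minimum gray distance to any strictly
    higher-ranked level, with ties resolved toward the lower gray; the
    top-ranked level's delta is its maximum distance to any other level.
    A singleton histogram gets delta = 1 by convention so gamma stays
    defined.

    Returns ``(delta, nn_higher, rank)`` aligned with ``levels``;
    ``nn_higher`` is the neighbor's gray level, -1 for the top.
    """
    n = len(levels)
    order = _rank_order(levels, rho, counts)
    delta = np.zeros(n, dtype=np.int64)
    nn = np.full(n, -1, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    top = order[0]
    if n == 1:
        delta[top] = 1
    else:
        delta[top] = np.abs(levels - levels[top]).max()
        for pos in range(1, n):
            i = order[pos]
            higher = order[:pos]
            d = np.abs(levels[higher] - levels[i])
            best = d.min()
            # argmin with ties resolved toward the lower gray level
            cand = levels[higher][d == best]
            delta[i] = best
            nn[i] = cand.min()
    return delta, nn, rank


def compute_gamma(rho: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Center score gamma = rho * delta, elementwise."""
    rho = np.asarray(rho)
    delta = np.asarray(delta)
    if rho.shape != delta.shape:
        raise ValueError("rho and delta must be aligned")
    return rho * delta


def build_profile(hist: GrayHistogram, d_c: float) -> DensityProfile:
    """Compute rho, delta and gamma for every present gray level."""
    levels, rho = compute_density(hist, d_c)
    counts = hist.counts[levels]
    delta, nn, rank = compute_delta(levels, rho, counts)
    gamma = compute_gamma(rho, delta)
    return DensityProfile(
        levels=levels, counts=counts, rho=rho, delta=delta, gamma=gamma,
        nn_higher=nn, rank=rank,
    )


def select_centers(profile: DensityProfile, k: int) -> np.ndarray:
    """The min(k, #levels) levels with the largest gamma, in descending
    gamma order; ties broken by larger rho, then lower gray."""
    if k < 2:
        raise ValueError("k must be at least 2")
    order = np.lexsort((profile.levels, -profile.rho, -profile.gamma))
    return profile.levels[order[: min(k, len(profile.levels))]]


def assign_labels(profile: DensityProfile, centers: np.ndarray) -> dict[int, int]:
    """Propagate cluster labels down the density ranking.

    Centers receive labels 0..effective_k-1 in descending-gamma order;
    every other level, visited from the densest down, inherits the label
    of its nearest higher-ranked level.
    """
    label: dict[int, int] = {int(g): i for i, g in enumerate(centers)}
    for idx in profile.rank_order:
        g = int(profile.levels[idx])
        if g in label:
            continue
        nn = int(profile.nn_higher[idx])
        # by construction nn ranks strictly higher, so it is already labeled
        assert nn in label, f"nearest-denser chain broken at level {g}"
        label[g] = label[nn]
    return label


def fit(hist: GrayHistogram, params: DPCParams) -> DPCModel:
    """Cluster a gray-level histogram with the given (d_c, k)."""
    profile = build_profile(hist, params.d_c)
    centers = select_centers(profile, params.k)
    level_label = assign_labels(profile, centers)
    return DPCModel(params=params, profile=profile, centers=centers,
                    level_label=level_label)


def decision_graph(profile: DensityProfile) -> pd.DataFrame:
    """The rho-delta decision graph as a table, one row per present
    level, sorted by gray (columns: gray, rho, delta, gamma)."""
    return pd.DataFrame(
        {
            "gray": profile.levels,
            "rho": profile.rho,
            "delta": profile.delta,
            "gamma": profile.gamma,
        }
    ).sort_values("gray", ignore_index=True)
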