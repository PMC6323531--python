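"""Segmentation fitness (entropy) and the SEC evaluation metric.

The optimizer's smell-concentration function is the Shannon entropy, in
bits, of the segmented image's cluster-frequency distribution: for
cluster frequencies q_c,  H = -sum_c q_c log2 q_c.  A richer, more
informative segmentation has higher entropy; H is bounded by
log2(effective_k) with equality iff the clusters are equally populated.

SEC scores inter-region contrast after the fact: clusters are ordered by
mean gray, and for each adjacent pair with sizes N, M and means U1, U2
the classical two-class between-class variance

    N/(N+M) (U1-U)^2 + M/(N+M) (U2-U)^2,   U = (N U1 + M U2)/(N+M)

is accumulated (algebraically equal to NM/(N+M)^2 (U1-U2)^2).  Larger SEC
means stronger contrast between neighboring regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import dpc_core
from .gray_io import GrayHistogram, GrayImage


@dataclass(frozen=True)
class SegmentedImage:
    """Cluster ids per pixel plus each cluster's mean source gray."""

    labels: np.ndarray
    cluster_mean_gray: dict[int, float]
    effective_k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        present = np.unique(labels)
        if present.min() < 0 or present.max() >= self.effective_k:
            raise ValueError("cluster ids must lie in [0, effective_k)")
        missing = [int(i) for i in present if int(i) not in self.cluster_mean_gray]
        if missing:
            raise ValueError(f"cluster_mean_gray missing ids {missing}")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)


def relabel_pixels(img: GrayImage, model: dpc_core.DPCModel) -> SegmentedImage:
    """Map every pixel to its gray level's cluster.

    Every gray value present in the image must be covered by the model's
    level -> label map (which it is when the model was fitted on the
    image's own histogram).
    """
    lut = np.full(256, -1, dtype=np.int64)
    for g, lab in model.level_label.items():
        lut[g] = lab
    labels = lut[img.pixels]
    if (labels < 0).any():
        unmapped = np.unique(img.pixels[labels < 0])
        raise ValueError(f"gray values {unmapped.tolist()} not in model")
    means = {}
    for lab in np.unique(labels):
        means[int(lab)] = float(img.pixels[labels == lab].mean())
    return SegmentedImage(labels=labels, cluster_mean_gray=means,
                          effective_k=model.effective_k)


def _entropy_bits(sizes: np.ndarray) -> float:
    sizes = np.asarray(sizes, dtype=float)
    q = sizes[sizes > 0] / sizes.sum()
    return float(-(q * np.log2(q)).sum())


def image_entropy(seg: SegmentedImage) -> float:
    """Shannon entropy, in bits, of the cluster-frequency distribution."""
    return _entropy_bits(np.bincount(seg.labels.ravel()))


def segmentation_entropy(hist: GrayHistogram, level_label: dict[int, int]) -> float:
    """Entropy of a segmentation computed directly from the histogram.

    Equivalent to :func:`image_entropy` of the relabeled image, but
    without touching pixels: cluster sizes are sums of level counts.
    """
    k = max(level_label.values()) + 1
    sizes = np.zeros(k)
    for g, lab in level_label.items():
        sizes[lab] += hist.counts[g]
    return _entropy_bits(sizes)


def sec(seg: SegmentedImage) -> float:
    """Between-class variance summed over adjacent-in-mean-gray cluster
    pairs; 0 for a single-cluster segmentation by convention."""
    sizes = np.bincount(seg.labels.ravel(), minlength=seg.effective_k)
    order = sorted(seg.cluster_mean_gray, key=seg.cluster_mean_gray.get)
    total = 0.0
    for a, b in zip(order, order[1:]):
        n, m = float(sizes[a]), float(sizes[b])
        if n == 0 or m == 0:
            continue
        u1 = seg.cluster_mean_gray[a]
        u2 = seg.cluster_mean_gray[b]
        u = (n * u1 + m * u2) / (n + m)
        total += n / (n + m) * (u1 - u) ** 2 + m / (n + m) * (u2 - u) ** 2
    return total


def make_entropy_fitness(
    hist: GrayHistogram, cache: bool = True
) -> Callable[[dpc_core.DPCParams], float]:
    """Smell-concentration function for the optimizers.

    Returns ``f(params) -> entropy_bits`` of the DPC segmentation of
    ``hist`` under ``params``.  Because only ceil(d_c) affects the
    clustering, evaluations are memoized per (ceil(d_c), k) cell when
    ``cache`` is on.
    """
    memo: dict[tuple[int, int], float] = {}

    def fitness(params: dpc_core.DPCParams) -> float:
        key = (int(np.ceil(params.d_c)), int(params.k))
        if not cache or key not in memo:
            model = dpc_core.fit(hist, params)
            value = segmentation_entropy(hist, model.level_label)
            if not cache:
                return value
            memo[key] = value
        return memo[key]

    return fitness
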