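"""Synthetic grayscale phantoms with ground-truth labels.

A phantom is a piecewise-constant image — a background gray plus
ellipse/rectangle regions at distinct grays, later regions overwriting
earlier ones — with optional additive Gaussian noise (rounded half-up,
clipped to 0..255).  Phantoms emulate the structure of brain CT/MRI
slices (lesion and edema regions on a darker background) closely enough
to exercise histogram-based segmentation, while providing the exact
pixel-level truth the real datasets lack.  Gaussian noise is a
simplification of real MRI noise (which is Rician); see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gray_io import GrayImage


@dataclass(frozen=True)
class Region:
    """One phantom region.

    ``shape`` is "ellipse" with geometry (cy, cx, ry, rx) or
    "rectangle" with geometry (r0, c0, r1, c1), end-exclusive.
    """

    shape: str
    geometry: tuple[float, ...]
    gray: int

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0 <= self.gray <= 255:
            raise ValueError("region gray must be in [0, 255]")

    def mask(self, size: tuple[int, int]) -> np.ndarray:
        h, w = size
        if self.shape == "ellipse":
            cy, cx, ry, rx = self.geometry
            if not (0 <= cy - ry and cy + ry < h and 0 <= cx - rx and cx + rx < w):
                raise ValueError(f"ellipse {self.geometry} out of bounds for {size}")
            yy, xx = np.mgrid[0:h, 0:w]
            return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        r0, c0, r1, c1 = (int(v) for v in self.geometry)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"rectangle {self.geometry} out of bounds for {size}")
        m = np.zeros((h, w), dtype=bool)
        m[r0:r1, c0:c1] = True
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom: canvas size, background gray, regions,
    Gaussian noise sigma (gray units) and RNG seed."""

    size: tuple[int, int] = (64, 64)
    background: int = 40
    regions: tuple[Region, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background <= 255:
            raise ValueError("background gray must be in [0, 255]")
        grays = [self.background] + [r.gray for r in self.regions]
        if len(set(grays)) != len(grays):
            raise ValueError("base grays must be distinct")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def base_grays(self) -> list[int]:
        """Background gray followed by each region's gray."""
        return [self.background] + [r.gray for r in self.regions]


def generate(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a phantom; returns the image and the truth label array
    (0 = background, i = i-th region, later regions overwrite)."""
    h, w = spec.size
    img = np.full((h, w), spec.background, dtype=float)
    truth = np.zeros((h, w), dtype=np.int64)
    for i, region in enumerate(spec.regions, start=1):
        m = region.mask(spec.size)
        img[m] = region.gray
        truth[m] = i
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255)
    return GrayImage(img.astype(np.int64)), truth


def match_and_score(pred_labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Pixel accuracy under the best one-to-one cluster <-> truth
    matching (Hungarian assignment on the confusion matrix)."""
    conf = _confusion(pred_labels, truth_labels)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(conf[rows, cols].sum() / conf.sum())


def merge_and_score(pred_labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Pixel accuracy after merging every predicted cluster onto the
    truth class it overlaps most (majority vote).

    Appropriate when the segmentation is finer than the truth (an
    entropy-maximal clustering splits each tissue class into many gray
    bands); a one-to-one matching would count all but one band of each
    class as errors.
    """
    conf = _confusion(pred_labels, truth_labels)
    return float(conf.max(axis=1).sum() / conf.sum())


def _confusion(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    np_pred = np.unique(pred, return_inverse=True)
    np_truth = np.unique(truth, return_inverse=True)
    conf = np.zeros((len(np_pred[0]), len(np_truth[0])), dtype=np.int64)
    np.add.at(conf, (np_pred[1], np_truth[1]), 1)
    return conf


def default_suite(base_seed: int = 0) -> list[PhantomSpec]:
    """Five standard 64x64 test phantoms of varying region count and
    noise level (base grays at least 60 apart, sigma up to 5)."""
    return [
        PhantomSpec(
            background=40, noise_sigma=0.0, seed=base_seed,
            regions=(Region("ellipse", (24, 24, 12, 9), 120),
                     Region("rectangle", (40, 38, 58, 60), 200)),
        ),
        PhantomSpec(
            background=40, noise_sigma=5.0, seed=base_seed + 1,
            regions=(Region("ellipse", (24, 24, 12, 9), 120),
                     Region("rectangle", (40, 38, 58, 60), 200)),
        ),
        PhantomSpec(
            background=30, noise_sigma=5.0, seed=base_seed + 2,
            regions=(Region("ellipse", (20, 20, 10, 14), 100),
                     Region("rectangle", (38, 6, 60, 26), 170),
                     Region("ellipse", (44, 46, 12, 12), 240)),
        ),
        PhantomSpec(
            background=50, noise_sigma=3.0, seed=base_seed + 3,
            regions=(Region("ellipse", (32, 32, 18, 22), 180),),
        ),
        PhantomSpec(
            background=20, noise_sigma=5.0, seed=base_seed + 4,
            regions=(Region("rectangle", (4, 4, 24, 30), 90),
                     Region("rectangle", (40, 34, 60, 60), 160),
                     Region("ellipse", (18, 46, 10, 12), 230)),
        ),
    ]
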