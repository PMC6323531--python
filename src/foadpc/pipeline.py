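"""End-to-end segmentation pipeline and JSON reporting.

``segment`` runs the full method on one image: build the gray-level
histogram, let the chosen optimizer (fruit-fly swarm, genetic algorithm
or exhaustive grid) pick (d_c, k) by maximizing the entropy of the
resulting density-peaks segmentation, relabel the pixels, and score the
result (entropy in bits, SEC).  The k-means baseline skips the
optimizer and quantizes the gray axis directly at a fixed k.

Every run is fully determined by its seed; reports serialize with
sorted keys and no timestamps, so equal seeds give byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
from pydantic import BaseModel

from . import baselines, dpc_core, fitness as fit_mod, foa_opt
from .foa_opt import ConfigError
from .gray_io import GrayHistogram, GrayImage, histogram

logger = logging.getLogger(__name__)

METHODS = ("foa", "ga", "grid", "kmeans")


@dataclass(frozen=True)
class PipelineConfig:
    """Run settings; defaults follow the reference setup (fruit-fly
    swarm: population 10, 10 generations; GA: population 10, 20
    generations; k-means baseline at k=7)."""

    method: str = "foa"
    pop: int = 10
    gen: int = 10
    ga_pop: int = 10
    ga_gen: int = 20
    kmeans_k: int = 7
    seed: int = 0
    step_low: float = -5.0
    step_high: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(
                f"unknown method {self.method!r}; choose from {METHODS}")
        if min(self.pop, self.gen, self.ga_pop, self.ga_gen) < 1:
            raise ConfigError("population and generation counts must be positive")
        if self.kmeans_k < 2:
            raise ConfigError("kmeans_k must be at least 2")
        if not self.step_low < self.step_high:
            raise ConfigError("step_low must be strictly below step_high")


class SegmentationReport(BaseModel):
    """JSON report schema shared by every method."""

    method: str
    seed: Optional[int]
    d_c: Optional[float]
    k: Optional[int]
    effective_k: int
    entropy_bits: float
    sec: float
    evaluations: Optional[int]
    trace: Optional[list[float]]
    image_height: int
    image_width: int
    settings: dict[str, float]


@dataclass(frozen=True)
class SegmentationResult:
    """Everything one run produces."""

    params: dpc_core.DPCParams | None
    model: dpc_core.DPCModel | None
    level_label: dict[int, int]
    seg: fit_mod.SegmentedImage
    entropy_bits: float
    sec: float
    trace: np.ndarray | None
    evaluations: int | None
    report: SegmentationReport

    @property
    def effective_k(self) -> int:
        return self.seg.effective_k

    def report_json(self) -> str:
        """Deterministic serialization: sorted keys, two-space indent."""
        return json.dumps(self.report.model_dump(), sort_keys=True, indent=2)


def segment(
    img: GrayImage,
    method: str = "foa",
    config: PipelineConfig | None = None,
    **overrides,
) -> SegmentationResult:
    """Segment an image with the chosen method (foa | ga | grid | kmeans)."""
    config = replace(config or PipelineConfig(), method=method, **overrides)
    hist = histogram(img)
    fitness = fit_mod.make_entropy_fitness(hist)

    params: dpc_core.DPCParams | None
    trace: np.ndarray | None
    evaluations: int | None
    if method == "foa":
        res = foa_opt.optimize(
            fitness,
            foa_opt.FOAConfig(sizepop=config.pop, maxgen=config.gen,
                              step_low=config.step_low,
                              step_high=config.step_high, seed=config.seed),
        )
        params, trace, evaluations = res.best_params, res.trace, res.evaluations
    elif method == "ga":
        res = baselines.ga_optimize(fitness, pop=config.ga_pop,
                                    gens=config.ga_gen, seed=config.seed)
        params, trace, evaluations = res.best_params, res.trace, res.evaluations
    elif method == "grid":
        res = baselines.grid_search(hist, fitness)
        params, trace = res.best_params, res.trace
        evaluations = res.trace.size
    elif method == "kmeans":
        params, trace, evaluations = None, None, None
    else:  # pragma: no cover - guarded by PipelineConfig
        raise ConfigError(f"unknown method {method!r}")

    model: dpc_core.DPCModel | None = None
    if params is not None:
        model = dpc_core.fit(hist, params)
        seg = fit_mod.relabel_pixels(img, model)
        level_label = model.level_label
    else:
        k = min(config.kmeans_k, len(hist.levels))
        if k < 2:
            raise ConfigError("k-means needs at least 2 present gray levels")
        level_label = baselines.kmeans_gray(hist, k, seed=config.seed)
        seg = _relabel_from_map(img, level_label)

    entropy = fit_mod.image_entropy(seg)
    sec_value = fit_mod.sec(seg)
    report = SegmentationReport(
        method=method,
        seed=config.seed,
        d_c=None if params is None else params.d_c,
        k=None if params is None else params.k,
        effective_k=seg.effective_k,
        entropy_bits=entropy,
        sec=sec_value,
        evaluations=evaluations,
        trace=None if trace is None else [float(t) for t in trace],
        image_height=img.height,
        image_width=img.width,
        settings={
            "pop": config.pop, "gen": config.gen,
            "ga_pop": config.ga_pop, "ga_gen": config.ga_gen,
            "kmeans_k": config.kmeans_k,
            "step_low": config.step_low, "step_high": config.step_high,
        },
    )
    logger.info("segment method=%s entropy=%.4f sec=%.2f effective_k=%d",
                method, entropy, sec_value, seg.effective_k)
    return SegmentationResult(
        params=params, model=model, level_label=level_label, seg=seg,
        entropy_bits=entropy, sec=sec_value, trace=trace,
        evaluations=evaluations, report=report,
    )


def _relabel_from_map(img: GrayImage, level_label: dict[int, int]) -> fit_mod.SegmentedImage:
    lut = np.full(256, -1, dtype=np.int64)
    for g, lab in level_label.items():
        lut[g] = lab
    labels = lut[img.pixels]
    if (labels < 0).any():
        raise ValueError("gray value not covered by the level-label map")
    means = {int(lab): float(img.pixels[labels == lab].mean())
             for lab in np.unique(labels)}
    return fit_mod.SegmentedImage(labels=labels, cluster_mean_gray=means,
                                  effective_k=int(labels.max()) + 1)


def report_schema() -> dict:
    """The published JSON schema of :class:`SegmentationReport`."""
    return SegmentationReport.model_json_schema()


def load_published_schema() -> dict:
    """The schema file shipped with the package (docs + validation)."""
    text = resources.files("foadpc").joinpath("report.schema.json").read_text()
    return json.loads(text)
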