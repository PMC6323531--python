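"""Grayscale image I/O and gray-level histograms.

The whole pipeline operates on the 256-bin gray-level histogram of an
8-bit image: the abscissa is the gray level (0..255), the ordinate is the
number of pixels at that level.  This module fixes the gray domain, loads
images into it deterministically, and writes label images back out.

Conversion rules (all deterministic):

* multi-channel images are reduced by the ITU-R BT.601 luma
  ``Y = 0.299 R + 0.587 G + 0.114 B``, rounded half-up;
* images deeper than 8 bits are rejected unless ``rescale=True``, in
  which case they are min-max rescaled onto 0..255 (round half-up).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

#: Number of gray levels in the fixed 8-bit domain.
GRAY_LEVELS = 256

# ITU-R BT.601 luma weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])


class GrayImageError(ValueError):
    """Invalid or unsupported image input."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale image: a 2-D array of integers in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise GrayImageError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise GrayImageError("image must contain at least one pixel")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.floor(px)):
                raise GrayImageError("pixel values must be integers")
            px = px.astype(np.int64)
        if px.min() < 0 or px.max() > 255:
            raise GrayImageError("pixel values must lie in [0, 255]")
        px = px.astype(np.uint8)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayHistogram:
    """Pixel counts per gray level 0..255; ``sum(counts) == total``."""

    counts: np.ndarray
    total: int = field(default=0)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (GRAY_LEVELS,):
            raise ValueError(f"counts must have shape ({GRAY_LEVELS},)")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        total = int(c.sum())
        if total < 1:
            raise ValueError("histogram must count at least one pixel")
        if self.total and self.total != total:
            raise ValueError("total does not match sum(counts)")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "total", total)

    @property
    def levels(self) -> np.ndarray:
        """Gray levels with at least one pixel, ascending."""
        return np.flatnonzero(self.counts)


def load_gray_image(path: str | os.PathLike, rescale: bool = False) -> GrayImage:
    """Read a PNG/PGM/TIFF file as an 8-bit grayscale image.

    Multi-channel inputs are converted by BT.601 luma (round half-up).
    Inputs deeper than 8 bits raise :class:`GrayImageError` unless
    ``rescale`` is set, in which case they are min-max rescaled to 0..255.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        mode = im.mode
        if mode == "1":
            arr = np.asarray(im.convert("L"))
        elif mode == "L":
            arr = np.asarray(im)
        elif mode in ("LA", "P", "PA"):
            arr = _luma(np.asarray(im.convert("RGB")))
        elif mode in ("RGB", "RGBA", "CMYK", "YCbCr"):
            arr = _luma(np.asarray(im.convert("RGB")))
        elif mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            if not rescale:
                raise GrayImageError(
                    f"{path}: bit depth exceeds 8 bits; pass rescale=True "
                    "to min-max rescale onto 0..255"
                )
            arr = _minmax_rescale(np.asarray(im, dtype=float))
        else:
            raise GrayImageError(f"{path}: unsupported image mode {mode!r}")
    return GrayImage(np.asarray(arr, dtype=np.int64))


def _luma(rgb: np.ndarray) -> np.ndarray:
    return _round_half_up(rgb[..., :3].astype(float) @ _LUMA)


def _minmax_rescale(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return _round_half_up((arr - lo) / (hi - lo) * 255.0)


def histogram(img: GrayImage) -> GrayHistogram:
    """Gray-level histogram: ``counts[g]`` = number of pixels equal to g."""
    counts = np.bincount(img.pixels.ravel(), minlength=GRAY_LEVELS)
    return GrayHistogram(counts.astype(np.int64))


def write_label_image(
    labels: np.ndarray, palette: dict[int, int], path: str | os.PathLike
) -> None:
    """Render a cluster-label array to an 8-bit PNG through ``palette``.

    ``palette`` maps every cluster id occurring in ``labels`` to an output
    gray value in [0, 255]; a missing id raises ``KeyError``.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    missing = [int(i) for i in present if int(i) not in palette]
    if missing:
        raise KeyError(f"palette missing cluster ids {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.uint8)
    for i in present:
        gray = palette[int(i)]
        if not 0 <= gray <= 255:
            raise ValueError(f"palette gray {gray} out of [0, 255]")
        lut[int(i)] = gray
    Image.fromarray(lut[labels], mode="L").save(path, format="PNG")


def mean_gray_palette(labels: np.ndarray, img: GrayImage) -> dict[int, int]:
    """Default palette: each cluster rendered at its mean source gray,
    rounded half-up."""
    labels = np.asarray(labels)
    if labels.shape != img.pixels.shape:
        raise ValueError("labels shape must match image shape")
    out: dict[int, int] = {}
    for i in np.unique(labels):
        mean = img.pixels[labels == i].mean()
        out[int(i)] = int(_round_half_up(mean))
    return out
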