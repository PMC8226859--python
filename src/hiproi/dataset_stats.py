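"""ROI-size statistics that drive anchor design.

The central quantity is the dimensionless ROI ratio: the side of a square
hip box divided by the long side of its image (after conceptual zero-padding
to a square, whose side *is* the long side).  The ratio makes boxes
comparable across datasets with wildly different resolutions, and its
empirical distribution is what the anchor scales are designed to cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .imaging_io import BoxAnnotation, Radiograph

__all__ = [
    "SizeSummary",
    "RatioDistribution",
    "roi_ratio",
    "summarize_sizes",
    "ratio_distribution",
    "ratio_histogram",
]


def _long_side(img: Radiograph | float | int) -> float:
    if isinstance(img, Radiograph):
        return float(img.long_side)
    return float(img)


@dataclass(frozen=True)
class SizeSummary:
    """Order statistics and moments of image long sides (pixels)."""

    n_images: int
    max: float
    min: float
    median: float
    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("SizeSummary requires n_images >= 1")
        if not (self.min <= self.median <= self.max):
            raise ValueError("inconsistent order statistics")


@dataclass(frozen=True)
class RatioDistribution:
    """Empirical distribution of ROI side / image long side."""

    ratios: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.size == 0:
            raise ValueError("RatioDistribution requires at least one ratio")
        if np.any(r <= 0) or np.any(r >= 1.5):
            raise ValueError("ROI ratios must lie in (0, 1.5)")
        if np.any(r > 1.0):
            warnings.warn("ROI ratio exceeds 1: box larger than the image long side")
        object.__setattr__(self, "ratios", r)

    @property
    def n(self) -> int:
        return int(self.ratios.size)

    @property
    def min(self) -> float:
        return float(self.ratios.min())

    @property
    def max(self) -> float:
        return float(self.ratios.max())

    @property
    def median(self) -> float:
        return float(np.median(self.ratios))

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())

    @property
    def std(self) -> float:
        return float(self.ratios.std(ddof=1)) if self.n > 1 else 0.0

    def percentile(self, p: float | Sequence[float]) -> float | np.ndarray:
        """Percentile(s) by linear interpolation between order statistics."""
        out = np.percentile(self.ratios, p, method="linear")
        return float(out) if np.ndim(out) == 0 else out


def roi_ratio(box: BoxAnnotation, img: Radiograph | float | int) -> float:
    """ROI side divided by the image long side (both in original pixels)."""
    long_side = _long_side(img)
    if long_side <= 0:
        raise ValueError("image long side must be positive")
    return box.side / long_side


def summarize_sizes(
    images: Iterable[Radiograph | float | int], ddof: int = 1
) -> SizeSummary:
    """Table-style summary of image long sides.

    ``ddof`` selects sample (1, default) or population (0) standard
    deviation; a single image yields std 0 either way.
    """
    sides = np.asarray([_long_side(im) for im in images], dtype=float)
    if sides.size == 0:
        raise ValueError("summarize_sizes requires at least one image")
    std = float(sides.std(ddof=ddof)) if sides.size > ddof else 0.0
    return SizeSummary(
        n_images=int(sides.size),
        max=float(sides.max()),
        min=float(sides.min()),
        median=float(np.median(sides)),
        mean=float(sides.mean()),
        std=std,
    )


def ratio_distribution(
    boxes: Sequence[BoxAnnotation],
    long_sides: Mapping[str, float | int],
    tag: str = "",
) -> RatioDistribution:
    """One ratio per box, using each box's own image long side."""
    if not boxes:
        raise ValueError("ratio_distribution requires at least one box")
    missing = sorted({b.image_id for b in boxes} - set(long_sides))
    if missing:
        raise KeyError(f"no image metadata for image_id(s): {', '.join(missing)}")
    ratios = np.array([roi_ratio(b, long_sides[b.image_id]) for b in boxes])
    return RatioDistribution(ratios, tag=tag)


def ratio_histogram(
    dist: RatioDistribution, bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts over fixed-width bins covering [0, max ratio]."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(dist.max / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist.ratios, bins=edges)
    return counts, edges
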