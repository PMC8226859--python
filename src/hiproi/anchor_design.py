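"""Data-driven anchor design for a single-feature-layer detector.

The detector predicts from one g x g grid of cells over a square model input
(default 224 px split 7 x 7, so each cell is 32 px).  Every cell carries K
square anchors whose side is ``scale * cell_px``.  The design procedure maps
an ROI-ratio coverage band observed in the data (e.g. 10%-31.4% of the image
side) onto K equally spaced scales, rounded to one decimal so that the band
(0.100, 0.314) yields the canonical set {0.7, 1.0, 1.3, 1.6, 1.9, 2.2}.

Anchors are never clipped at image borders: clipping would shrink corner
anchors and break the coverage guarantee, and IoU handles out-of-bounds area
naturally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["GridSpec", "ScaleSet", "AnchorSet", "coverage", "design_scales", "generate_anchors"]


@dataclass(frozen=True)
class GridSpec:
    """Square model input split into a uniform grid of square cells."""

    input_px: int = 224
    grid_n: int = 7

    def __post_init__(self) -> None:
        if self.input_px < 1 or self.grid_n < 1:
            raise ValueError("input_px and grid_n must be positive")
        if self.input_px % self.grid_n != 0:
            raise ValueError(
                f"grid_n ({self.grid_n}) must divide input_px ({self.input_px}) evenly"
            )

    @property
    def cell_px(self) -> int:
        return self.input_px // self.grid_n


@dataclass(frozen=True)
class ScaleSet:
    """Ordered anchor scales (multipliers of cell_px) with their provenance."""

    scales: tuple[float, ...]
    ratio_lo: float | None = None
    ratio_hi: float | None = None

    def __post_init__(self) -> None:
        if len(self.scales) < 1:
            raise ValueError("ScaleSet requires at least one scale")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if any(b >= a for a, b in zip(self.scales[1:], self.scales)):
            raise ValueError("scales must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.scales)


@dataclass(frozen=True)
class AnchorSet:
    """The materialized grid of square anchors in model-space pixels.

    ``boxes`` is an (N, 4) float array of (cx, cy, w, h); ``records`` lists
    (cell_i, cell_j, scale, cx, cy, side) with cell_i the column index and
    cell_j the row index.  Ordering is row-major over cells with scales
    innermost, matching the detection head's output layout.
    """

    grid: GridSpec
    scales: ScaleSet
    boxes: np.ndarray
    records: tuple[tuple[int, int, float, float, float, float], ...]
    aspect_ratios: tuple[float, ...] = (1.0,)

    @property
    def count(self) -> int:
        return int(self.boxes.shape[0])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "input_px": self.grid.input_px,
            "grid_n": self.grid.grid_n,
            "scales": list(self.scales.scales),
            "ratio_lo": self.scales.ratio_lo,
            "ratio_hi": self.scales.ratio_hi,
            "aspect_ratios": list(self.aspect_ratios),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnchorSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        grid = GridSpec(doc["input_px"], doc["grid_n"])
        scales = ScaleSet(tuple(doc["scales"]), doc.get("ratio_lo"), doc.get("ratio_hi"))
        return generate_anchors(scales, grid, tuple(doc.get("aspect_ratios", [1.0])))


def coverage(scale: float, grid: GridSpec = GridSpec()) -> float:
    """Fraction of the model input side covered by an anchor of this scale."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * grid.cell_px / grid.input_px


def design_scales(
    ratio_lo: float, ratio_hi: float, k: int = 6, grid: GridSpec = GridSpec()
) -> ScaleSet:
    """K equally spaced scales whose coverages span [ratio_lo, ratio_hi].

    The endpoint scales are ``ratio * input_px / cell_px`` rounded to one
    decimal, and the K interpolated values are rounded to one decimal too;
    with the default 224/7/32 grid and band (0.100, 0.314) this reproduces
    {0.7, 1.0, 1.3, 1.6, 1.9, 2.2}.  Rounding collapse (duplicate scales)
    is an error: use smaller K or wider bounds.
    """
    if not (0 < ratio_lo < ratio_hi <= 1):
        raise ValueError("require 0 < ratio_lo < ratio_hi <= 1")
    if k < 2:
        raise ValueError("require K >= 2")
    s_min = round(ratio_lo * grid.input_px / grid.cell_px, 1)
    s_max = round(ratio_hi * grid.input_px / grid.cell_px, 1)
    raw = np.linspace(s_min, s_max, k)
    scales = tuple(round(float(s), 1) for s in raw)
    if len(set(scales)) < k or any(b >= a for a, b in zip(scales[1:], scales)):
        raise ValueError(
            f"scale rounding collapse for bounds ({ratio_lo}, {ratio_hi}) with K={k}: "
            f"got {scales}; use a smaller K or wider ratio bounds"
        )
    return ScaleSet(scales, ratio_lo=ratio_lo, ratio_hi=ratio_hi)


def generate_anchors(
    scales: ScaleSet,
    grid: GridSpec = GridSpec(),
    aspect_ratios: Sequence[float] = (1.0,),
) -> AnchorSet:
    """Materialize one anchor per (cell, scale, aspect) at cell centers.

    For cell (i, j) and scale s the anchor is centered at
    ``((i+0.5)*cell_px, (j+0.5)*cell_px)`` with side ``s*cell_px``; a
    non-unit aspect ratio a stretches it to w = side*sqrt(a), h =
    side/sqrt(a) (escape hatch for non-square ROIs; default 1:1 only).
    Anchors extending past the input border are kept unclipped.
    """
    cell = grid.cell_px
    records: list[tuple[int, int, float, float, float, float]] = []
    boxes: list[tuple[float, float, float, float]] = []
    for j in range(grid.grid_n):  # rows (y)
        for i in range(grid.grid_n):  # columns (x)
            cx, cy = (i + 0.5) * cell, (j + 0.5) * cell
            for s in scales.scales:
                side = s * cell
                for a in aspect_ratios:
                    w, h = side * a**0.5, side / a**0.5
                    records.append((i, j, s, cx, cy, side))
                    boxes.append((cx, cy, w, h))
    return AnchorSet(
        grid=grid,
        scales=scales,
        boxes=np.asarray(boxes, dtype=np.float64),
        records=tuple(records),
        aspect_ratios=tuple(aspect_ratios),
    )
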