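"""Synthetic pseudo-pelvic radiographs with ground-truth hip boxes.

Each sample is a grayscale image containing a smooth background gradient, a
faint pelvic-ring ellipse, and two bright filled discs standing in for the
femoral heads, placed roughly symmetrically about the vertical midline.
The ground-truth square box for each hip is the disc diameter times a
loose-fit margin (default 1.3, jittered +/-10% to emulate annotator
variability), centered on the disc up to a small jitter ("approximately
centered").  Image long sides follow three heterogeneity profiles echoing
high-resolution hospital films, lower-resolution study archives, and a
mixed web-sourced collection.

Realism is deliberately minimal: the generator targets the statistical
structure that drives anchor design and evaluation (image-size spread, ROI
ratio band, object/background contrast), not anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .imaging_io import (
    BoxAnnotation,
    Radiograph,
    write_annotations_coco,
    write_annotations_csv,
)

__all__ = ["SIZE_PROFILES", "ARTIFACT_MODES", "SynthConfig", "SynthSample",
           "generate_sample", "generate_samples", "generate_dataset"]

#: long-side ranges (pixels) of the three image-size heterogeneity profiles
SIZE_PROFILES: dict[str, tuple[int, int]] = {
    "high_res": (1616, 4280),
    "low_res": (466, 1080),
    "mixed": (225, 4256),
}

ARTIFACT_MODES = ("text_overlay", "implant_disc", "collapsed_head", "dislocation_offset")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``ratio_range`` is the band of box side / image long side the hips are
    drawn from; ``margin`` is the loose-fit factor between disc diameter and
    box side, jittered by ``margin_jitter`` (relative).  ``artifact_modes``
    lists scenario tags applied at random to samples (implants, text
    overlays, collapsed heads, dislocations); empty means clean images.
    """

    n_images: int = 200
    size_profile: str = "mixed"
    ratio_range: tuple[float, float] = (0.10, 0.30)
    artifact_modes: tuple[str, ...] = ()
    noise_sd: float = 6.0
    margin: float = 1.3
    margin_jitter: float = 0.10
    center_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.ratio_range
        if not (0 < lo < hi < 1):
            raise ValueError("ratio_range must satisfy 0 < lo < hi < 1")
        if self.size_profile not in SIZE_PROFILES:
            raise ValueError(f"size_profile must be one of {sorted(SIZE_PROFILES)}")
        unknown = set(self.artifact_modes) - set(ARTIFACT_MODES)
        if unknown:
            raise ValueError(f"unknown artifact modes: {sorted(unknown)}")


@dataclass(frozen=True)
class SynthSample:
    radiograph: Radiograph
    boxes: tuple[BoxAnnotation, BoxAnnotation]
    tags: tuple[str, ...] = ()


def _fill_disc(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    """Paint a filled disc, computing only over its bounding window."""
    h, w = img.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = value


def _ellipse_ring(
    img: np.ndarray, cx: float, cy: float, ax: float, ay: float, width: float, value: float
) -> None:
    h, w = img.shape
    x0, x1 = max(int(cx - ax - width) - 1, 0), min(int(cx + ax + width) + 2, w)
    y0, y1 = max(int(cy - ay - width) - 1, 0), min(int(cy + ay + width) + 2, h)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    rel = width / max(ax, ay)
    mask = (d >= (1 - rel) ** 2) & (d <= (1 + rel) ** 2)
    img[y0:y1, x0:x1][mask] += value


def generate_sample(
    cfg: SynthConfig, rng: np.random.Generator, image_id: str = "synth_000"
) -> SynthSample:
    """One pseudo-radiograph with exactly two non-overlapping hip boxes.

    Deterministic given the generator state.  Raises if the configured
    ratio band is infeasible for the drawn image size (box side < 4 px).
    """
    lo_px, hi_px = SIZE_PROFILES[cfg.size_profile]
    long_side = int(rng.integers(lo_px, hi_px + 1))
    aspect = float(rng.uniform(0.72, 0.95))
    portrait = bool(rng.random() < 0.15)
    short_side = max(int(round(long_side * aspect)), 1)
    if portrait:
        w, h = short_side, long_side
    else:
        w, h = long_side, short_side

    # background: smooth two-axis gradient
    base = rng.uniform(20.0, 40.0)
    tilt_v = rng.uniform(10.0, 40.0)
    tilt_h = rng.uniform(-15.0, 15.0)
    img = (
        base
        + tilt_v * (np.arange(h, dtype=np.float32) / max(h - 1, 1))[:, None]
        + tilt_h * (np.arange(w, dtype=np.float32) / max(w - 1, 1))[None, :]
    ).astype(np.float32)

    # faint pelvic ring
    _ellipse_ring(
        img, w / 2, 0.42 * h, 0.33 * w, 0.30 * h, max(0.012 * long_side, 2.0),
        rng.uniform(25.0, 45.0),
    )

    tags: tuple[str, ...] = ()
    if cfg.artifact_modes:
        tags = tuple(m for m in cfg.artifact_modes if rng.random() < 0.5)

    ratio = float(rng.uniform(*cfg.ratio_range))
    side = ratio * long_side
    if side < 4:
        raise ValueError(
            f"ratio_range {cfg.ratio_range} infeasible for image long side {long_side}"
        )

    # symmetric disc placement with jitter; retry until boxes are disjoint
    y_c = 0.52 * h
    boxes: list[BoxAnnotation] = []
    discs: list[tuple[float, float, float, float]] = []  # cx, cy, r, intensity
    for attempt in range(60):
        boxes.clear()
        discs.clear()
        dx = rng.uniform(0.17, 0.28) * w
        ok = True
        for hip, sign in (("right", -1.0), ("left", +1.0)):  # patient right on image left
            m = cfg.margin * (1.0 + rng.uniform(-cfg.margin_jitter, cfg.margin_jitter))
            d_cx = w / 2 + sign * (dx + rng.uniform(-0.02, 0.02) * w)
            d_cy = y_c + rng.uniform(-0.04, 0.04) * h
            if "dislocation_offset" in tags and hip == "left":
                d_cx += rng.uniform(-0.05, 0.05) * long_side
                d_cy -= rng.uniform(0.02, 0.06) * long_side
            r = side / m / 2.0
            jx = rng.uniform(-cfg.center_jitter, cfg.center_jitter) * side
            jy = rng.uniform(-cfg.center_jitter, cfg.center_jitter) * side
            intensity = rng.uniform(150.0, 215.0)
            discs.append((d_cx, d_cy, r, intensity))
            boxes.append(BoxAnnotation(image_id, d_cx + jx, d_cy + jy, side, hip))
        (a, b) = boxes
        if abs(a.cx - b.cx) >= side or abs(a.cy - b.cy) >= side:
            break
        ok = False
    else:
        raise ValueError("could not place two disjoint hip boxes; widen the image profile")

    for k, (d_cx, d_cy, r, intensity) in enumerate(discs):
        _fill_disc(img, d_cx, d_cy, r, intensity)
        if "collapsed_head" in tags and k == 1:
            # crescent: carve an offset disc out of the head
            _fill_disc(img, d_cx + 0.45 * r, d_cy - 0.25 * r, 0.75 * r,
                       intensity - rng.uniform(60.0, 90.0))
        if "implant_disc" in tags and k == 0:
            # prosthetic head: brighter core plus a stem
            _fill_disc(img, d_cx, d_cy, 0.7 * r, min(intensity + 40.0, 250.0))
            sw = max(int(0.35 * r), 1)
            y1 = min(int(d_cy + 3.5 * r), img.shape[0])
            img[int(d_cy) : y1, int(d_cx - sw) : int(d_cx + sw)] = min(intensity + 30.0, 250.0)

    if "text_overlay" in tags:
        # blocky bright "text" marks near the top-left corner
        ch = max(int(0.02 * long_side), 3)
        for t in range(int(rng.integers(2, 5))):
            x0 = int(0.03 * w + t * 1.8 * ch)
            img[int(0.04 * h) : int(0.04 * h) + ch, x0 : x0 + ch] = 240.0

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SynthSample(Radiograph(pixels, source_id=image_id), (boxes[0], boxes[1]), tags)


def generate_samples(cfg: SynthConfig) -> list[SynthSample]:
    """All ``cfg.n_images`` samples in memory, deterministic for a seed."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    width = max(len(str(cfg.n_images - 1)), 3)
    return [
        generate_sample(cfg, rng, image_id=f"synth_{i:0{width}d}")
        for i in range(cfg.n_images)
    ]


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> list[SynthSample]:
    """Write PNG images, CSV + COCO annotations, and a JSON manifest."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(cfg)
    boxes: list[BoxAnnotation] = []
    sizes: dict[str, tuple[int, int]] = {}
    for s in samples:
        Image.fromarray(s.radiograph.pixels).save(img_dir / f"{s.radiograph.source_id}.png")
        boxes.extend(s.boxes)
        sizes[s.radiograph.source_id] = (s.radiograph.width, s.radiograph.height)
    write_annotations_csv(boxes, out_dir / "annotations.csv")
    write_annotations_coco(boxes, sizes, out_dir / "annotations.json")
    manifest = {"config": asdict(cfg), "n_images": cfg.n_images,
                "image_dir": "images", "tags": {s.radiograph.source_id: list(s.tags)
                                                for s in samples if s.tags}}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return samples
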