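"""Image and annotation I/O plus the preprocessing chain.

Every radiograph is normalized to 8-bit grayscale, zero-padded to a square
and resized to the model input size (default 224 px).  The geometric part of
that chain is recorded in a :class:`GeomTransform` so that boxes round-trip
exactly between original-image and model coordinates.

Coordinate convention: 0-based continuous pixel coordinates; a box is stored
as center ``(cx, cy)`` plus side length and is converted to half-open
corner intervals only when areas are needed.  Padding is appended on the
right/bottom, which keeps the origin fixed (left/top pads are zero but the
transform supports either placement).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "Radiograph",
    "BoxAnnotation",
    "GeomTransform",
    "normalize_to_8bit",
    "pad_to_square",
    "resize_to_model",
    "preprocess",
    "box_to_model_space",
    "box_to_original_space",
    "read_image",
    "read_annotations",
    "read_coco_image_sizes",
    "write_annotations_csv",
    "write_annotations_coco",
]

HIP_SIDES = ("left", "right")

#: header of the plain-text annotation format
CSV_HEADER = ["image_id", "hip_side", "cx", "cy", "side"]


@dataclass(frozen=True)
class Radiograph:
    """A 2-D grayscale image with provenance.

    ``pixels`` is a 2-D uint8 array after normalization; ``long_side`` is the
    maximum of width and height and is the size statistic all ROI ratios are
    normalized by.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("Radiograph requires a non-empty 2-D pixel array")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def long_side(self) -> int:
        return max(self.width, self.height)


@dataclass(frozen=True)
class BoxAnnotation:
    """Square ROI in original-image pixel coordinates.

    The box is square by construction (one side length).  Loose-fitting
    labels may extend past the image border; only the center is required to
    lie within the image.
    """

    image_id: str
    cx: float
    cy: float
    side: float
    hip_side: str = "left"

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError(f"box side must be positive, got {self.side}")
        if self.hip_side not in HIP_SIDES:
            raise ValueError(f"hip_side must be one of {HIP_SIDES}, got {self.hip_side!r}")

    def corners(self) -> tuple[float, float, float, float]:
        """Half-open corner interval ``(x0, y0, x1, y1)``."""
        h = self.side / 2.0
        return (self.cx - h, self.cy - h, self.cx + h, self.cy + h)


@dataclass(frozen=True)
class GeomTransform:
    """Affine map ``x' = (x + pad) * scale`` from original to model space.

    ``pad_x``/``pad_y`` are the zero-padding offsets added on the left/top
    (zero under the default right/bottom placement); ``scale`` is the resize
    factor from the padded square to model space.
    """

    pad_x: float = 0.0
    pad_y: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("scale must be non-zero")

    def compose(self, after: "GeomTransform") -> "GeomTransform":
        """The transform equivalent to applying ``self`` then ``after``."""
        return GeomTransform(
            pad_x=self.pad_x + after.pad_x / self.scale,
            pad_y=self.pad_y + after.pad_y / self.scale,
            scale=self.scale * after.scale,
        )

    def inverse(self) -> "GeomTransform":
        return GeomTransform(
            pad_x=-self.pad_x * self.scale,
            pad_y=-self.pad_y * self.scale,
            scale=1.0 / self.scale,
        )

    def apply_point(self, x: float, y: float) -> tuple[float, float]:
        return (x + self.pad_x) * self.scale, (y + self.pad_y) * self.scale

    def apply_box(self, box: BoxAnnotation) -> BoxAnnotation:
        cx, cy = self.apply_point(box.cx, box.cy)
        return replace(box, cx=cx, cy=cy, side=box.side * abs(self.scale))


def normalize_to_8bit(
    raw: np.ndarray, bit_depth: int | None = None, source_id: str = ""
) -> Radiograph:
    """Linearly rescale an intensity array onto [0, 255].

    The input's min–max range is mapped to the full 8-bit range and rounded
    to integers; a constant image maps to all zeros.  ``bit_depth`` (8 or 16)
    is validated against the value range when given.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty array")
    if bit_depth is not None:
        if bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
        if arr.max() > 2**bit_depth - 1 or arr.min() < 0:
            raise ValueError(f"values outside the declared {bit_depth}-bit range")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros(arr.shape, dtype=np.uint8)
    else:
        out = np.rint((arr - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return Radiograph(out, source_id=source_id)


def pad_to_square(img: Radiograph) -> tuple[Radiograph, GeomTransform]:
    """Zero-pad to ``long_side x long_side`` (pad appended right/bottom)."""
    s = img.long_side
    if img.width == img.height:
        return img, GeomTransform()
    out = np.zeros((s, s), dtype=img.pixels.dtype)
    out[: img.height, : img.width] = img.pixels
    return Radiograph(out, source_id=img.source_id), GeomTransform()


def resize_to_model(
    img: Radiograph, model_size: int = 224
) -> tuple[Radiograph, GeomTransform]:
    """Bilinearly resize a square image to ``model_size`` per side."""
    if img.width != img.height:
        raise ValueError(f"resize_to_model requires a square input, got {img.width}x{img.height}")
    scale = model_size / img.width
    if img.width == model_size:
        return img, GeomTransform(scale=1.0)
    pil = Image.fromarray(img.pixels)
    out = np.asarray(pil.resize((model_size, model_size), Image.Resampling.BILINEAR))
    return Radiograph(out, source_id=img.source_id), GeomTransform(scale=scale)


def preprocess(
    img: Radiograph, model_size: int = 224
) -> tuple[Radiograph, GeomTransform]:
    """Pad to square then resize to model space; returns the composed map."""
    squared, t_pad = pad_to_square(img)
    resized, t_resize = resize_to_model(squared, model_size=model_size)
    return resized, t_pad.compose(t_resize)


def box_to_model_space(box: BoxAnnotation, t: GeomTransform) -> BoxAnnotation:
    return t.apply_box(box)


def box_to_original_space(box: BoxAnnotation, t: GeomTransform) -> BoxAnnotation:
    return t.inverse().apply_box(box)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_image(path: str | Path, normalize: bool = True) -> Radiograph:
    """Read a PNG/JPEG radiograph (8- or 16-bit) as an 8-bit Radiograph."""
    path = Path(path)
    pil = Image.open(path)
    if pil.mode in ("RGB", "RGBA", "P"):
        pil = pil.convert("L")
    arr = np.asarray(pil)
    source_id = path.stem
    if normalize:
        return normalize_to_8bit(arr, source_id=source_id)
    return Radiograph(arr.astype(np.uint8), source_id=source_id)


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return "csv"
    if path.suffix.lower() == ".json":
        return "coco_json"
    raise ValueError(f"cannot infer annotation format from {path.name}")


def read_annotations(path: str | Path, format: str | None = None) -> list[BoxAnnotation]:
    """Read square-box annotations from CSV or COCO-style JSON.

    CSV columns are ``image_id,hip_side,cx,cy,side``.  COCO boxes are
    ``(x, y, w, h)`` with ``w == h`` expected; a non-square box triggers a
    warning and is symmetrized to ``side = max(w, h)`` (loose fitting).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "coco_json":
        return _read_coco(path)[0]
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_csv(path: Path) -> list[BoxAnnotation]:
    boxes: list[BoxAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return boxes
    if [c.strip() for c in rows[0]] != CSV_HEADER:
        raise ValueError(f"line 1: expected header {','.join(CSV_HEADER)}")
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(CSV_HEADER):
            raise ValueError(f"line {lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}")
        image_id, hip_side = row[0].strip(), row[1].strip()
        try:
            cx, cy, side = (float(v) for v in row[2:5])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coordinate ({exc})") from None
        try:
            boxes.append(BoxAnnotation(image_id, cx, cy, side, hip_side))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return boxes


def _read_coco(path: Path) -> tuple[list[BoxAnnotation], dict[str, tuple[int, int]]]:
    with open(path) as fh:
        doc = json.load(fh)
    id_to_name: dict[int, str] = {}
    sizes: dict[str, tuple[int, int]] = {}
    for im in doc.get("images", []):
        name = Path(im.get("file_name", str(im["id"]))).stem
        id_to_name[im["id"]] = name
        if "width" in im and "height" in im:
            sizes[name] = (int(im["width"]), int(im["height"]))
    boxes: list[BoxAnnotation] = []
    for ann in doc.get("annotations", []):
        x, y, w, h = (float(v) for v in ann["bbox"])
        if w != h:
            warnings.warn(
                f"non-square COCO box {ann['bbox']} symmetrized to side={max(w, h)}",
                stacklevel=3,
            )
        side = max(w, h)
        image_id = id_to_name.get(ann["image_id"], str(ann["image_id"]))
        hip_side = ann.get("hip_side", ann.get("attributes", {}).get("hip_side"))
        if hip_side not in HIP_SIDES:
            # fall back to image-side position (patient left appears image right)
            width = sizes.get(image_id, (2 * (x + w / 2), 0))[0]
            hip_side = "left" if (x + w / 2) >= width / 2 else "right"
        boxes.append(BoxAnnotation(image_id, x + w / 2.0, y + h / 2.0, side, hip_side))
    return boxes, sizes


def read_coco_image_sizes(path: str | Path) -> dict[str, tuple[int, int]]:
    """Image ``(width, height)`` per image id from a COCO-style JSON file."""
    return _read_coco(Path(path))[1]


def write_annotations_csv(boxes: Iterable[BoxAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for b in boxes:
            # repr round-trips floats exactly
            writer.writerow([b.image_id, b.hip_side, repr(b.cx), repr(b.cy), repr(b.side)])


def write_annotations_coco(
    boxes: Sequence[BoxAnnotation],
    sizes: Mapping[str, tuple[int, int]],
    path: str | Path,
    file_suffix: str = ".png",
) -> None:
    """Write boxes + image sizes as COCO-style JSON (single category "hip")."""
    image_ids = sorted({b.image_id for b in boxes} | set(sizes))
    id_of = {name: k + 1 for k, name in enumerate(image_ids)}
    images = [
        {
            "id": id_of[name],
            "file_name": f"{name}{file_suffix}",
            "width": sizes[name][0],
            "height": sizes[name][1],
        }
        for name in image_ids
        if name in sizes
    ]
    annotations = []
    for k, b in enumerate(boxes, start=1):
        x0, y0, _, _ = b.corners()
        annotations.append(
            {
                "id": k,
                "image_id": id_of[b.image_id],
                "category_id": 1,
                "bbox": [x0, y0, b.side, b.side],
                "area": b.side * b.side,
                "iscrowd": 0,
                "hip_side": b.hip_side,
            }
        )
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "hip"}],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
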