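"""Annotation, resizing, augmentation and dataset-split protocol.

Label scheme: background = 0, grain = 1, impurity = 2.  Annotations are
LabelMe-style JSON polygons; masks are single-channel PNGs holding the
literal values 0/1/2.  Rasterization uses the even-odd rule evaluated at
integer pixel centres (0-based, x rightward, y downward); when polygons
overlap, the later one in the list wins.

Images are resized bilinearly, masks with nearest-neighbour so the label
set stays inside {0,1,2}.  The augmentation protocol produces exactly six
variants per original - 90 deg and 270 deg counter-clockwise rotations,
0.6x and 1.8x rescalings (restored to the original canvas by background
padding / centre cropping), and horizontal and vertical mirrors - so an
augmented split holds 7x the original images (350 -> 2450, 50 -> 350).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LABEL_NAMES",
    "NAME_TO_LABEL",
    "PolygonAnnotation",
    "DatasetSplit",
    "read_labelme",
    "write_labelme",
    "rasterize",
    "resize_pair",
    "resize_image",
    "resize_mask",
    "augment",
    "augment_dataset",
    "split_dataset",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
]

LABEL_NAMES = {0: "background", 1: "grain", 2: "impurity"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass(frozen=True)
class PolygonAnnotation:
    """One labelled polygon: label in {0,1,2}, >= 3 vertices."""

    label: int
    points: tuple[tuple[float, float], ...]
    source_image: str = ""

    def __post_init__(self):
        if self.label not in LABEL_NAMES:
            raise ValueError(f"label must be one of {sorted(LABEL_NAMES)}")
        if len(self.points) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    val: tuple
    test: tuple
    seed: int


# ---------------------------------------------------------------------------
# LabelMe JSON
# ---------------------------------------------------------------------------

def read_labelme(json_path) -> list[PolygonAnnotation]:
    """Parse a LabelMe JSON file into polygon annotations."""
    json_path = Path(json_path)
    try:
        doc = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed LabelMe JSON in {json_path}: {exc}") from exc
    annotations = []
    for shape in doc.get("shapes", []):
        name = shape.get("label")
        if name not in NAME_TO_LABEL:
            raise ValueError(
                f"unknown label {name!r} in {json_path}; "
                f"expected one of {sorted(NAME_TO_LABEL)}"
            )
        points = tuple((float(x), float(y)) for x, y in shape["points"])
        annotations.append(
            PolygonAnnotation(
                label=NAME_TO_LABEL[name],
                points=points,
                source_image=doc.get("imagePath", ""),
            )
        )
    return annotations


def write_labelme(json_path, annotations, image_path: str, width: int, height: int):
    doc = {
        "version": "3.16.7",
        "flags": {},
        "shapes": [
            {
                "label": LABEL_NAMES[a.label],
                "points": [[float(x), float(y)] for x, y in a.points],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for a in annotations
        ],
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": height,
        "imageWidth": width,
    }
    Path(json_path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _fill_polygon(points: np.ndarray, width: int, height: int) -> np.ndarray:
    """Even-odd interior test at integer pixel centres, vectorised by row.

    A pixel (x, y) is inside when the number of polygon-edge crossings of
    the ray {(u, y): u > x} is odd; edges are treated half-open in y so a
    vertex is counted once.
    """
    inside = np.zeros((height, width), dtype=bool)
    x1, y1 = points[:, 0], points[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    dy = y2 - y1
    keep = dy != 0  # horizontal edges never cross a horizontal ray
    x1, y1, x2, y2, dy = x1[keep], y1[keep], x2[keep], y2[keep], dy[keep]
    if x1.size == 0:
        return inside
    slope = (x2 - x1) / dy
    ylo = np.minimum(y1, y2)
    yhi = np.maximum(y1, y2)
    y0 = max(0, int(np.ceil(ylo.min())))
    y3 = min(height - 1, int(np.floor(np.max(yhi))))
    xs = np.arange(width)
    for y in range(y0, y3 + 1):
        crossing = (ylo <= y) & (y < yhi)
        if not crossing.any():
            continue
        xi = x1[crossing] + (y - y1[crossing]) * slope[crossing]
        xi.sort()
        # crossings strictly right of the pixel centre
        n_right = xi.size - np.searchsorted(xi, xs, side="right")
        inside[y] = (n_right % 2) == 1
    return inside


def rasterize(annotations, width: int, height: int) -> np.ndarray:
    """Burn polygons into a {0,1,2} label mask; later polygons win overlaps."""
    mask = np.zeros((height, width), dtype=np.uint8)
    for ann in annotations:
        pts = np.asarray(ann.points, dtype=np.float64)
        if _polygon_area(pts) == 0.0:
            warnings.warn(
                f"skipping degenerate polygon (zero area) labelled "
                f"{LABEL_NAMES[ann.label]!r}",
                stacklevel=2,
            )
            continue
        mask[_fill_polygon(pts, width, height)] = ann.label
    return mask


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, target: tuple[int, int] = (512, 512)) -> np.ndarray:
    """Bilinear resize of an RGB image to (width, height)."""
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target size must be positive")
    if image.shape[1] == tw and image.shape[0] == th:
        return image.copy()
    return np.asarray(
        Image.fromarray(image).resize((tw, th), Image.BILINEAR)
    )


def resize_mask(mask: np.ndarray, target: tuple[int, int] = (512, 512)) -> np.ndarray:
    """Nearest-neighbour resize of a label mask (labels stay in {0,1,2})."""
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target size must be positive")
    if mask.shape[1] == tw and mask.shape[0] == th:
        return mask.copy()
    return np.asarray(
        Image.fromarray(mask.astype(np.uint8)).resize((tw, th), Image.NEAREST)
    )


def resize_pair(image, mask, target: tuple[int, int] = (512, 512)):
    return resize_image(image, target), resize_mask(mask, target)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rescale_keep_canvas(image, mask, factor: float):
    """Rescale both arrays, then restore the original canvas size.

    Shrinking pads with background (zeros); enlarging centre-crops.
    """
    h, w = mask.shape
    nw, nh = max(1, round(w * factor)), max(1, round(h * factor))
    im = resize_image(image, (nw, nh))
    mk = resize_mask(mask, (nw, nh))
    if factor < 1.0:
        out_im = np.zeros_like(image)
        out_mk = np.zeros_like(mask)
        oy, ox = (h - nh) // 2, (w - nw) // 2
        out_im[oy : oy + nh, ox : ox + nw] = im
        out_mk[oy : oy + nh, ox : ox + nw] = mk
        return out_im, out_mk
    oy, ox = (nh - h) // 2, (nw - w) // 2
    return im[oy : oy + h, ox : ox + w], mk[oy : oy + h, ox : ox + w]


def augment(image: np.ndarray, mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """The six geometric variants of one aligned (image, mask) pair."""
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask are not aligned")
    variants = [
        (np.rot90(image, 1).copy(), np.rot90(mask, 1).copy()),   # 90 deg CCW
        (np.rot90(image, 3).copy(), np.rot90(mask, 3).copy()),   # 270 deg CCW
        _rescale_keep_canvas(image, mask, 0.6),
        _rescale_keep_canvas(image, mask, 1.8),
        (image[:, ::-1].copy(), mask[:, ::-1].copy()),           # horizontal mirror
        (image[::-1].copy(), mask[::-1].copy()),                 # vertical mirror
    ]
    return variants


def augment_dataset(pairs):
    """Originals plus their six variants: len(out) == 7 * len(pairs)."""
    out = []
    for image, mask in pairs:
        out.append((image, mask))
        out.extend(augment(image, mask))
    return out


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_dataset(files, counts=(350, 50, 100), seed: int = 0) -> DatasetSplit:
    """Random disjoint train/val/test assignment, reproducible under seed."""
    files = list(files)
    n_train, n_val, n_test = counts
    need = n_train + n_val + n_test
    if len(files) < need:
        raise ValueError(
            f"need {need} files for counts {tuple(counts)}, got {len(files)}"
        )
    order = np.random.default_rng(seed).permutation(len(files))
    pick = lambda sl: tuple(files[i] for i in order[sl])
    return DatasetSplit(
        train=pick(slice(0, n_train)),
        val=pick(slice(n_train, n_train + n_val)),
        test=pick(slice(n_train + n_val, need)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PNG IO
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, image: np.ndarray):
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    mask = np.asarray(Image.open(path))
    if mask.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel")
    return mask.astype(np.uint8)


def write_mask(path, mask: np.ndarray):
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)
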