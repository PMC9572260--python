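"""Synthetic grain-pile scenes with exact ground truth.

Renders piles of convex grain blobs (ellipses) and elongated impurity
fragments (bent straw strips and thin husk arcs) on a dark background.
Every object is a polygon, burned into the label mask in draw order (later
objects overwrite earlier ones at overlaps), so the stored LabelMe-style
polygons re-rasterize to the stored mask exactly and per-pixel class
labels and pixel counts are known by construction.

A :class:`MassModel` attaches masses to pixel counts - grams of grain and
impurity per 1000 pixels, with optional multiplicative lognormal-free
Gaussian noise - so the pixel-to-mass quantification chain can be tested
against a known truth.  The default densities give a grain of roughly 300
pixels the thousand-kernel weight of the field wheat they emulate
(~46.9 g per 1000 grains) and a grain/impurity per-kilopixel mass ratio of
exactly 11.8906, the laboratory-calibrated value shipped as the package
default.

All randomness flows from the single integer seed of the
:class:`SceneSpec`; the same spec renders bit-for-bit identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .datasets import (
    PolygonAnnotation,
    rasterize,
    write_image,
    write_labelme,
    write_mask,
    _fill_polygon,
)
from .quantify import DEFAULT_DELTA, CalibrationSample, PixelCounts

__all__ = [
    "SceneSpec",
    "MassModel",
    "RenderedSample",
    "render_scene",
    "sample_masses",
    "make_dataset",
    "sample_calibration",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered grain-pile scene."""

    image_width: int = 512
    image_height: int = 512
    n_grains: int = 120
    n_impurities: int = 8
    grain_axis_range: tuple[float, float] = (9.0, 16.0)  # ellipse semi-axes, px
    impurity_length_range: tuple[float, float] = (60.0, 140.0)
    impurity_width_range: tuple[float, float] = (4.0, 9.0)
    grain_color: tuple[int, int, int] = (184, 152, 96)
    impurity_color: tuple[int, int, int] = (206, 196, 150)
    background_color: tuple[int, int, int] = (40, 38, 34)
    color_jitter: float = 14.0  # per-object RGB std
    blur_sigma: float = 0.8  # px
    noise_std: float = 4.0  # intensity units
    seed: int = 0

    def __post_init__(self):
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_grains < 0 or self.n_impurities < 0:
            raise ValueError("object counts must be non-negative")
        side = min(self.image_width, self.image_height)
        lo_a, hi_a = self.grain_axis_range
        if not 0 < lo_a <= hi_a or 2 * hi_a >= side:
            raise ValueError(
                f"grain axes {self.grain_axis_range} do not fit a "
                f"{self.image_width}x{self.image_height} canvas"
            )
        lo_l, hi_l = self.impurity_length_range
        lo_w, hi_w = self.impurity_width_range
        if not 0 < lo_l <= hi_l or hi_l >= side:
            raise ValueError(
                f"impurity lengths {self.impurity_length_range} do not fit a "
                f"{self.image_width}x{self.image_height} canvas"
            )
        if not 0 < lo_w <= hi_w or hi_w >= side:
            raise ValueError("impurity widths must be positive and fit the canvas")


@dataclass(frozen=True)
class MassModel:
    """Grams carried per 1000 pixels of each class, with relative noise."""

    grain_mass_per_kpx: float = 0.1565
    impurity_mass_per_kpx: float = 0.1565 / DEFAULT_DELTA
    noise_cv: float = 0.05

    def __post_init__(self):
        if self.grain_mass_per_kpx <= 0 or self.impurity_mass_per_kpx <= 0:
            raise ValueError("mass densities must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def true_delta(self) -> float:
        return self.grain_mass_per_kpx / self.impurity_mass_per_kpx


@dataclass(frozen=True)
class RenderedSample:
    image: np.ndarray  # uint8 (H, W, 3)
    mask: np.ndarray  # uint8 (H, W), values 0/1/2
    true_counts: PixelCounts
    polygons: tuple[PolygonAnnotation, ...]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse_polygon(cx, cy, a, b, angle, n_vertices=22):
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return tuple(
        (float(cx + ca * xi - sa * yi), float(cy + sa * xi + ca * yi))
        for xi, yi in zip(x, y)
    )


def _strip_polygon(rng, start, length, width):
    """Piecewise-linear bent strip (straw fragment)."""
    n_seg = int(rng.integers(2, 5))
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pts = [np.asarray(start, dtype=float)]
    for k in range(n_seg):
        if k:
            heading += rng.normal(0.0, 0.35)
        step = np.array([np.cos(heading), np.sin(heading)]) * (length / n_seg)
        pts.append(pts[-1] + step)
    pts = np.asarray(pts)
    # vertex normals: perpendicular to the averaged adjacent segment directions
    seg = np.diff(pts, axis=0)
    seg /= np.linalg.norm(seg, axis=1, keepdims=True)
    vdir = np.vstack([seg[0], (seg[:-1] + seg[1:]) / 2.0, seg[-1]])
    vdir /= np.maximum(np.linalg.norm(vdir, axis=1, keepdims=True), 1e-9)
    normal = np.stack([-vdir[:, 1], vdir[:, 0]], axis=1)
    half = width / 2.0
    left = pts + half * normal
    right = pts - half * normal
    return tuple(map(tuple, np.vstack([left, right[::-1]])))


def _husk_polygon(rng, center, length, width):
    """Thin partial annulus (husk fragment)."""
    span = rng.uniform(1.2, 2.4)
    radius = max(length / span, width)
    a0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.linspace(a0, a0 + span, 14)
    cx, cy = center
    outer = np.stack(
        [cx + (radius + width / 2) * np.cos(t), cy + (radius + width / 2) * np.sin(t)],
        axis=1,
    )
    inner = np.stack(
        [cx + (radius - width / 2) * np.cos(t), cy + (radius - width / 2) * np.sin(t)],
        axis=1,
    )
    return tuple(map(tuple, np.vstack([outer, inner[::-1]])))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_scene(spec: SceneSpec) -> RenderedSample:
    """Render one scene; deterministic in ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_width, spec.image_height

    polygons: list[PolygonAnnotation] = []
    for _ in range(spec.n_grains):
        a = rng.uniform(*spec.grain_axis_range)
        b = rng.uniform(spec.grain_axis_range[0], a)  # grains are oblong
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        polygons.append(
            PolygonAnnotation(
                label=1,
                points=_ellipse_polygon(cx, cy, a, b, rng.uniform(0, np.pi)),
            )
        )
    # impurities drawn last: straw and husks lie on top of the pile
    for _ in range(spec.n_impurities):
        length = rng.uniform(*spec.impurity_length_range)
        width = rng.uniform(*spec.impurity_width_range)
        origin = (rng.uniform(0, w), rng.uniform(0, h))
        if rng.uniform() < 0.7:
            pts = _strip_polygon(rng, origin, length, width)
        else:
            pts = _husk_polygon(rng, origin, length, width)
        polygons.append(PolygonAnnotation(label=2, points=pts))

    mask = np.zeros((h, w), dtype=np.uint8)
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = spec.background_color
    base = {1: np.asarray(spec.grain_color, float),
            2: np.asarray(spec.impurity_color, float)}
    for ann in polygons:
        region = _fill_polygon(np.asarray(ann.points, dtype=np.float64), w, h)
        mask[region] = ann.label
        color = base[ann.label] + rng.normal(0.0, spec.color_jitter, 3)
        image[region] = color

    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, (spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_std > 0:
        image += rng.normal(0.0, spec.noise_std, image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    return RenderedSample(
        image=image,
        mask=mask,
        true_counts=PixelCounts.from_mask(mask),
        polygons=tuple(polygons),
    )


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

def sample_masses(counts: PixelCounts, model: MassModel, seed: int = 0):
    """Simulate weighing the rendered sample: returns (w, w_z) in grams.

    Each component mass is its per-kilopixel density times pixel count
    per 1000, perturbed multiplicatively by Gaussian noise with the
    model's coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    noise_g, noise_z = 1.0, 1.0
    if model.noise_cv > 0:
        noise_g = max(0.0, 1.0 + rng.normal(0.0, model.noise_cv))
        noise_z = max(0.0, 1.0 + rng.normal(0.0, model.noise_cv))
    w_z = model.impurity_mass_per_kpx * counts.t_z / 1000.0 * noise_z
    w_grain = model.grain_mass_per_kpx * counts.t_w / 1000.0 * noise_g
    return w_grain + w_z, w_z


def sample_calibration(
    n_samples: int,
    spec: SceneSpec | None = None,
    model: MassModel | None = None,
    seed: int = 0,
) -> list[CalibrationSample]:
    """Render ``n_samples`` scenes and weigh them with the mass model."""
    spec = spec if spec is not None else SceneSpec()
    model = model if model is not None else MassModel()
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_samples)
    out = []
    for i in range(n_samples):
        scene_spec = dataclasses.replace(spec, seed=int(seeds[2 * i]))
        sample = render_scene(scene_spec)
        w, w_z = sample_masses(sample.true_counts, model, seed=int(seeds[2 * i + 1]))
        out.append(CalibrationSample(counts=sample.true_counts, w=w, w_z=w_z))
    return out


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def make_dataset(
    spec: SceneSpec,
    n_images: int,
    out_dir,
    seed: int = 0,
    mass_model: MassModel | None = None,
) -> pd.DataFrame:
    """Write ``n_images`` rendered scenes as PNG + mask + LabelMe JSON.

    Returns (and writes as ``manifest.csv``) a manifest listing the files,
    the true per-class pixel counts and - when a mass model is supplied -
    simulated sample masses.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc

    seeds = np.random.SeedSequence(seed).generate_state(2 * n_images)
    rows = []
    for i in range(n_images):
        scene_spec = dataclasses.replace(spec, seed=int(seeds[2 * i]))
        sample = render_scene(scene_spec)
        img_name = f"image_{i:04d}.png"
        mask_name = f"mask_{i:04d}.png"
        json_name = f"image_{i:04d}.json"
        try:
            write_image(out_dir / img_name, sample.image)
            write_mask(out_dir / mask_name, sample.mask)
            write_labelme(
                out_dir / json_name,
                sample.polygons,
                image_path=img_name,
                width=spec.image_width,
                height=spec.image_height,
            )
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / img_name}: {exc}") from exc
        row = {
            "image": img_name,
            "mask": mask_name,
            "json": json_name,
            "t_w": sample.true_counts.t_w,
            "t_z": sample.true_counts.t_z,
        }
        if mass_model is not None:
            w, w_z = sample_masses(
                sample.true_counts, mass_model, seed=int(seeds[2 * i + 1])
            )
            row["w"] = w
            row["w_z"] = w_z
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
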