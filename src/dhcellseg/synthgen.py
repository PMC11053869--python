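"""Seeded generator of synthetic microscopy-like scenes with instance masks.

Cells are ellipses with a low-order sinusoidal radial perturbation, placed
under a pairwise-overlap constraint, rendered at a foreground intensity over
a darker background, blurred and corrupted with Gaussian noise (8-bit
grayscale).  Later cells occlude earlier ones in the image, but every
instance's full mask is kept as ground truth, the way annotators label
partially occluded cells.

Presets emulate four microscopy regimes: few large strongly-deformed cells
(``u373_like``), many small low-contrast cells (``gowt1_like``), complex
shapes at low contrast (``simplus01_like``), high size variance with partial
occlusion (``simplus02_like``), and adherent/overlapping cells of varying
size (``t24_like``).  An additional ``easy`` preset (well-separated bright
blobs) exists for smoke-training and end-to-end tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from . import coco_io

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "PackingError",
    "generate_scene",
    "dataset_preset",
    "generate_dataset",
    "PRESETS",
]


class PackingError(RuntimeError):
    """The minimum cell count cannot be placed under the overlap constraint."""


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters of one scene (intensities on the 8-bit scale)."""

    image_size: tuple[int, int] = (256, 256)  # (height, width)
    cell_count: tuple[int, int] = (5, 10)     # inclusive range
    radius_range: tuple[float, float] = (8.0, 20.0)
    perturbation: float = 0.2                 # radial amplitude in [0, 1)
    max_overlap: float = 0.0                  # fraction of the smaller mask
    fg_intensity: float = 140.0
    bg_intensity: float = 60.0
    noise_std: float = 8.0
    blur_radius: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if not 0 <= self.max_overlap < 1:
            raise ValueError(f"max_overlap must lie in [0, 1), got {self.max_overlap}")
        if not 0 <= self.perturbation < 1:
            raise ValueError(f"perturbation must lie in [0, 1), got {self.perturbation}")
        for v in (self.fg_intensity, self.bg_intensity):
            if not 0 <= v <= 255:
                raise ValueError(f"intensities must lie in [0, 255], got {v}")


@dataclass
class SyntheticScene:
    """Rendered image plus full (pre-occlusion) per-instance ground truth."""

    image: np.ndarray                 # (H, W) uint8
    instances: list[np.ndarray]       # boolean (H, W) masks
    params: SceneParams
    records: list[dict] = field(default_factory=list)  # per-instance area/bbox

    def as_rgb(self) -> np.ndarray:
        """8-bit grayscale replicated to 3 channels for detector input."""
        return np.repeat(self.image[:, :, None], 3, axis=2)


def _cell_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    perturbation: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Rasterize one radially perturbed ellipse on pixel centres.

    The boundary in the ellipse frame is rho(theta) = 1 + amp * sum_k
    a_k cos(k theta + phi_k) with sum |a_k| = 1, so rho stays within
    [1 - amp, 1 + amp] and the shape is star-convex about its centre.
    """
    h, w = shape
    cy, cx = centre
    a, b = axes
    ii, jj = np.mgrid[0:h, 0:w]
    x = (jj + 0.5) - cx
    y = (ii + 0.5) - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * x + sa * y) / a
    v = (-sa * x + ca * y) / b
    rnorm = np.hypot(u, v)
    theta = np.arctan2(v, u)
    rho = np.ones_like(theta)
    if perturbation > 0:
        weights = np.abs(harmonics) / np.sum(np.abs(harmonics))
        for k, (wk, ph) in enumerate(zip(weights, phases), start=2):
            rho += perturbation * wk * np.cos(k * theta + ph)
    return rnorm <= rho


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate one scene deterministically from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    n_cells = int(rng.integers(params.cell_count[0], params.cell_count[1] + 1))
    masks: list[np.ndarray] = []
    attempts = 0
    while len(masks) < n_cells:
        if attempts >= 1000:
            if len(masks) >= params.cell_count[0]:
                break
            raise PackingError(
                f"placed only {len(masks)}/{params.cell_count[0]} cells "
                f"after {attempts} attempts at max_overlap={params.max_overlap}"
            )
        attempts += 1
        a = rng.uniform(*params.radius_range)
        b = rng.uniform(*params.radius_range)
        margin = max(a, b) * (1 + params.perturbation)
        if 2 * margin >= min(h, w):
            continue
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        angle = rng.uniform(0, np.pi)
        harmonics = rng.uniform(0.3, 1.0, size=2)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        cand = _cell_mask((h, w), (cy, cx), (a, b), angle,
                          params.perturbation, harmonics, phases)
        if not cand.any():
            continue
        ok = True
        for m in masks:
            inter = np.logical_and(cand, m).sum()
            limit = params.max_overlap * min(cand.sum(), m.sum())
            if inter > limit:
                ok = False
                break
        if ok:
            masks.append(cand)
    image = np.full((h, w), params.bg_intensity, dtype=float)
    for m in masks:  # z-order: later cells paint over earlier ones
        jitter = rng.normal(0, 0.05 * abs(params.fg_intensity - params.bg_intensity))
        image[m] = params.fg_intensity + jitter
    if params.blur_radius > 0:
        image = ndimage.gaussian_filter(image, params.blur_radius)
    image += rng.normal(0, params.noise_std, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    records = []
    for m in masks:
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        records.append({
            "area": int(m.sum()),
            "bbox": [int(cols[0]), int(rows[0]),
                     int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1)],
        })
    return SyntheticScene(image=image, instances=masks, params=params,
                          records=records)


PRESETS: dict[str, SceneParams] = {
    # few large, strongly deformed, adherent glioblastoma-like cells
    "u373_like": SceneParams(
        image_size=(256, 256), cell_count=(2, 5), radius_range=(18.0, 38.0),
        perturbation=0.35, max_overlap=0.0, fg_intensity=150.0,
        bg_intensity=60.0, noise_std=8.0, blur_radius=1.5,
    ),
    # many small, low-contrast fluorescent nuclei
    "gowt1_like": SceneParams(
        image_size=(256, 256), cell_count=(15, 25), radius_range=(5.0, 10.0),
        perturbation=0.10, max_overlap=0.0, fg_intensity=95.0,
        bg_intensity=60.0, noise_std=7.0, blur_radius=1.0,
    ),
    # complex morphology at low foreground/background contrast
    "simplus01_like": SceneParams(
        image_size=(256, 256), cell_count=(8, 14), radius_range=(8.0, 18.0),
        perturbation=0.30, max_overlap=0.0, fg_intensity=105.0,
        bg_intensity=70.0, noise_std=10.0, blur_radius=1.5,
    ),
    # high scale variance (max/min radius >= 3) with partial occlusion
    "simplus02_like": SceneParams(
        image_size=(256, 256), cell_count=(6, 12), radius_range=(6.0, 24.0),
        perturbation=0.20, max_overlap=0.25, fg_intensity=140.0,
        bg_intensity=50.0, noise_std=8.0, blur_radius=1.2,
    ),
    # adherent/overlapping bladder-cancer-like cells of varying size
    "t24_like": SceneParams(
        image_size=(256, 256), cell_count=(5, 12), radius_range=(8.0, 30.0),
        perturbation=0.30, max_overlap=0.30, fg_intensity=130.0,
        bg_intensity=70.0, noise_std=8.0, blur_radius=1.5,
    ),
    # well-separated bright blobs for smoke training / end-to-end tests
    "easy": SceneParams(
        image_size=(128, 128), cell_count=(4, 6), radius_range=(9.0, 15.0),
        perturbation=0.10, max_overlap=0.0, fg_intensity=200.0,
        bg_intensity=30.0, noise_std=3.0, blur_radius=0.8,
    ),
}


def dataset_preset(name: str) -> SceneParams:
    """Fixed parameter bundle for one of the documented dataset regimes."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def preset_yaml(name: str) -> str:
    """YAML dump of a preset's parameters."""
    return yaml.safe_dump(asdict(dataset_preset(name)), sort_keys=False)


def generate_dataset(
    preset, n_images: int, seed: int, out_dir,
) -> dict:
    """Write PNGs + one COCO annotation file + a deterministic 80/20 split.

    ``preset`` is a preset name or a :class:`SceneParams`; scene i uses seed
    ``seed + i``.  Returns a manifest dict with image paths, the annotation
    path, and the train/test file-name lists.
    """
    if n_images < 2:
        raise ValueError("n_images must be >= 2")
    params = dataset_preset(preset) if isinstance(preset, str) else preset
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    for i in range(n_images):
        scene = generate_scene(
            SceneParams(**{**asdict(params), "seed": seed + i}))
        fname = f"scene_{i:04d}.png"
        Image.fromarray(scene.image).save(out_dir / fname)
        h, w = scene.image.shape
        images.append(coco_io.ImageRecord(
            id=i + 1, file_name=fname, width=w, height=h))
        for mask in scene.instances:
            annotations.append(coco_io.annotation_from_mask(
                ann_id, i + 1, 1, mask))
            ann_id += 1
    annset = coco_io.AnnotationSet(
        info={"description": "synthetic microscopy-like scenes",
              "seed": seed, "preset": preset if isinstance(preset, str) else "custom"},
        licenses=[{"id": 1, "name": "synthetic"}],
        images=images,
        annotations=annotations,
        categories=[coco_io.CategoryRecord(id=1, name="cell")],
    )
    ann_path = out_dir / "annotations.json"
    coco_io.write_annotations(annset, ann_path)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    n_test = max(1, round(0.2 * n_images))
    test_idx = sorted(order[:n_test].tolist())
    train_idx = sorted(order[n_test:].tolist())
    split = {
        "train": [images[i].file_name for i in train_idx],
        "test": [images[i].file_name for i in test_idx],
    }
    with open(out_dir / "split.json", "w") as fh:
        json.dump(split, fh, indent=1)
    return {
        "annotations": str(ann_path),
        "images": [str(out_dir / im.file_name) for im in images],
        "split": split,
    }
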