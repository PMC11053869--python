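"""COCO-dialect (MS COCO 2014) annotation JSON I/O and polygon/mask conversion.

The annotation file carries five sections — info, licenses, images,
annotations, categories — with instance outlines stored as polygons (flat
``[x0, y0, x1, y1, ...]`` coordinate lists, possibly several rings per
instance).  Coordinates are 0-based pixel units, x rightward and y downward;
bounding boxes are ``(x, y, w, h)`` half-open.

Rasterization uses pixel-centre inclusion with even-odd semantics across
rings: a pixel (row i, col j) is inside a ring iff the point
``(j + 0.5, i + 0.5)`` is, and the fills of all rings of one instance are
XOR-combined, so interior rings cut holes.  Mask-to-polygon tracing emits
rings along pixel boundaries (integer coordinates), which makes the
polygon -> mask -> polygon round trip exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import shapely
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.polygon import orient

logger = logging.getLogger("dhcellseg")

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ImageRecord",
    "AnnotationRecord",
    "CategoryRecord",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "polygon_to_mask",
    "mask_to_polygon",
    "annotation_from_mask",
    "decode_rle",
]


class SchemaError(ValueError):
    """A required field is missing or malformed."""


class IntegrityError(ValueError):
    """A cross-reference (image id, category id) does not resolve."""


Polygons = list[list[float]]


@dataclass
class ImageRecord:
    id: int
    file_name: str
    width: int
    height: int
    date_captured: str = ""


@dataclass
class AnnotationRecord:
    id: int
    image_id: int
    category_id: int
    segmentation: Union[Polygons, dict]  # polygon rings, or RLE dict if iscrowd
    bbox: list[float]  # (x, y, w, h)
    area: float
    iscrowd: int = 0


@dataclass
class CategoryRecord:
    id: int
    name: str
    supercategory: str = ""


@dataclass
class AnnotationSet:
    info: dict = field(default_factory=dict)
    licenses: list[dict] = field(default_factory=list)
    images: list[ImageRecord] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    categories: list[CategoryRecord] = field(default_factory=list)

    def image_by_id(self, image_id: int) -> ImageRecord:
        for im in self.images:
            if im.id == image_id:
                return im
        raise IntegrityError(f"unknown image id {image_id}")

    def annotations_for(self, image_id: int) -> list[AnnotationRecord]:
        return [a for a in self.annotations if a.image_id == image_id]

    def validate(self, check_boxes: bool = False) -> None:
        """Check references, polygon sanity and (optionally) box tightness."""
        image_ids = {im.id for im in self.images}
        category_ids = {c.id for c in self.categories}
        for im in self.images:
            if im.width <= 0 or im.height <= 0:
                raise SchemaError(f"image {im.id}: non-positive dimensions")
        for ann in self.annotations:
            if ann.image_id not in image_ids:
                raise IntegrityError(
                    f"annotation {ann.id}: unknown image id {ann.image_id}")
            if ann.category_id not in category_ids:
                raise IntegrityError(
                    f"annotation {ann.id}: unknown category id {ann.category_id}")
            if isinstance(ann.segmentation, dict):
                continue  # RLE; decoded on demand
            im = self.image_by_id(ann.image_id)
            for ring in ann.segmentation:
                if len(ring) < 6 or len(ring) % 2:
                    raise SchemaError(
                        f"annotation {ann.id}: polygon needs >= 3 (x, y) vertices")
                xs, ys = np.asarray(ring[0::2]), np.asarray(ring[1::2])
                if (xs < 0).any() or (ys < 0).any() or \
                        (xs > im.width).any() or (ys > im.height).any():
                    raise SchemaError(
                        f"annotation {ann.id}: polygon exceeds image bounds")
            if check_boxes:
                mask = self.mask_for(ann)
                if mask.any():
                    rows = np.flatnonzero(mask.any(axis=1))
                    cols = np.flatnonzero(mask.any(axis=0))
                    tight = (cols[0], rows[0],
                             cols[-1] - cols[0] + 1, rows[-1] - rows[0] + 1)
                    if any(abs(b - t) > 1.0 for b, t in zip(ann.bbox, tight)):
                        raise SchemaError(
                            f"annotation {ann.id}: bbox {ann.bbox} not within "
                            f"1 px of tight box {tight}")

    def mask_for(self, ann: AnnotationRecord) -> np.ndarray:
        im = self.image_by_id(ann.image_id)
        if isinstance(ann.segmentation, dict):
            return decode_rle(ann.segmentation)
        return polygon_to_mask(ann.segmentation, im.width, im.height)


def _require(record: dict, key: str, context: str):
    if key not in record:
        raise SchemaError(f"{context}: missing required field {key!r}")
    return record[key]


def read_annotations(path) -> AnnotationSet:
    """Load and validate a five-section COCO-style JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    for section in ("info", "licenses", "images", "annotations", "categories"):
        if section not in raw:
            raise SchemaError(f"missing top-level section {section!r}")
    images = [
        ImageRecord(
            id=_require(im, "id", "image"),
            file_name=_require(im, "file_name", f"image {im.get('id')}"),
            width=_require(im, "width", f"image {im.get('id')}"),
            height=_require(im, "height", f"image {im.get('id')}"),
            date_captured=im.get("date_captured", ""),
        )
        for im in raw["images"]
    ]
    annotations = [
        AnnotationRecord(
            id=_require(a, "id", "annotation"),
            image_id=_require(a, "image_id", f"annotation {a.get('id')}"),
            category_id=_require(a, "category_id", f"annotation {a.get('id')}"),
            segmentation=_require(a, "segmentation", f"annotation {a.get('id')}"),
            bbox=list(_require(a, "bbox", f"annotation {a.get('id')}")),
            area=float(_require(a, "area", f"annotation {a.get('id')}")),
            iscrowd=int(a.get("iscrowd", 0)),
        )
        for a in raw["annotations"]
    ]
    categories = [
        CategoryRecord(
            id=_require(c, "id", "category"),
            name=_require(c, "name", f"category {c.get('id')}"),
            supercategory=c.get("supercategory", ""),
        )
        for c in raw["categories"]
    ]
    out = AnnotationSet(
        info=dict(raw["info"]),
        licenses=list(raw["licenses"]),
        images=images,
        annotations=annotations,
        categories=categories,
    )
    out.validate()
    return out


def write_annotations(annset: AnnotationSet, path) -> None:
    """Write the set as COCO-style JSON with a stable key order."""
    annset.validate()
    payload = {
        "info": annset.info,
        "licenses": annset.licenses,
        "images": [asdict(im) for im in annset.images],
        "annotations": [asdict(a) for a in annset.annotations],
        "categories": [asdict(c) for c in annset.categories],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)


# ---------------------------------------------------------------------------
# Polygon <-> mask


def _rings_of(segmentation: Polygons) -> list[np.ndarray]:
    return [np.asarray(ring, dtype=float).reshape(-1, 2) for ring in segmentation]


def _shoelace(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_to_mask(segmentation: Polygons, width: int, height: int) -> np.ndarray:
    """Rasterize polygon ring(s) to a (height, width) boolean mask.

    Pixel-centre sampling, rings XOR-combined (even-odd): interior rings cut
    holes.  A degenerate (zero-area) polygon yields an empty mask with a
    logged warning.
    """
    if isinstance(segmentation, dict):
        return decode_rle(segmentation)
    if segmentation and np.isscalar(segmentation[0]):
        segmentation = [segmentation]  # single flat ring
    mask = np.zeros((height, width), dtype=bool)
    for ring in _rings_of(segmentation):
        if len(ring) < 3 or _shoelace(ring) == 0.0:
            logger.warning("degenerate polygon (area 0) rasterized as empty")
            continue
        # sample only the ring's bounding box for speed
        j0 = max(int(np.floor(ring[:, 0].min())), 0)
        j1 = min(int(np.ceil(ring[:, 0].max())), width)
        i0 = max(int(np.floor(ring[:, 1].min())), 0)
        i1 = min(int(np.ceil(ring[:, 1].max())), height)
        if j1 <= j0 or i1 <= i0:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        centres = np.column_stack([jj.ravel() + 0.5, ii.ravel() + 0.5])
        closed = np.vstack([ring, ring[:1]])
        inside = MplPath(closed, closed=True).contains_points(centres)
        mask[i0:i1, j0:j1] ^= inside.reshape(i1 - i0, j1 - j0)
    return mask


def _poly_rings(poly: Polygon) -> Polygons:
    poly = orient(poly)  # exterior CCW, interiors CW
    rings = [np.asarray(poly.exterior.coords)[:-1]]
    rings += [np.asarray(r.coords)[:-1] for r in poly.interiors]
    return [ring.ravel().tolist() for ring in rings]


def mask_to_polygon(mask) -> list[Polygons]:
    """Trace each 4-connected component into pixel-boundary polygon rings.

    Returns one ring list per component (first ring the outer boundary,
    further rings holes); all vertices are integer pixel corners, so
    rasterizing with :func:`polygon_to_mask` reproduces the mask exactly.
    An empty mask yields an empty list.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)  # 4-connectivity
    out: list[Polygons] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        squares = shapely.box(cols.astype(float), rows.astype(float),
                              cols + 1.0, rows + 1.0)
        merged = shapely.union_all(squares)
        if isinstance(merged, MultiPolygon):  # corner-touching pinch case
            rings: Polygons = []
            for g in merged.geoms:
                rings.extend(_poly_rings(g))
            out.append(rings)
        else:
            out.append(_poly_rings(merged))
    return out


def annotation_from_mask(
    ann_id: int, image_id: int, category_id: int, mask: np.ndarray
) -> AnnotationRecord:
    """Build a polygon annotation (bbox, area from the mask) for one instance."""
    mask = np.asarray(mask).astype(bool)
    components = mask_to_polygon(mask)
    rings: Polygons = [r for comp in components for r in comp]
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = [float(cols[0]), float(rows[0]),
            float(cols[-1] - cols[0] + 1), float(rows[-1] - rows[0] + 1)] \
        if rows.size else [0.0, 0.0, 0.0, 0.0]
    return AnnotationRecord(
        id=ann_id,
        image_id=image_id,
        category_id=category_id,
        segmentation=rings,
        bbox=bbox,
        area=float(mask.sum()),
        iscrowd=0,
    )


def decode_rle(rle: dict) -> np.ndarray:
    """Decode uncompressed COCO RLE ({'counts': [...], 'size': [h, w]})."""
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, str):
        raise SchemaError("compressed RLE strings are not supported")
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((w, h)).T  # COCO RLE is column-major
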