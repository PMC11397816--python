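"""Annotation and raster formats touched by the canopy pipeline.

Supports the VGG Image Annotator (VIA 2.x) polygon JSON produced during
ground-truth labelling, COCO-style JSON (polygon segmentations, no RLE),
per-image normalised polygon text lines, binary mask rasters, and the
640x540 grid tiling used to cut camera frames into training tiles.

Coordinate conventions: pixel coordinates are 0-based, origin at the
top-left, (x, y) = (column, row); COCO bbox is [x, y, w, h] with (x, y) the
top-left corner. Rasterisation uses the pixel-centre inclusion rule with
boundary centres counted as foreground.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

log = logging.getLogger(__name__)

CLASS_NAMES = ("fruit", "branch")
CATEGORY_IDS = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}


@dataclass
class PolygonAnnotation:
    """One labelled polygon region on an image."""

    image_id: str
    class_label: str
    vertices: np.ndarray          # (N, 2) float (x, y) px
    instance_id: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bbox(self) -> tuple:
        """COCO-style [x, y, w, h]."""
        x0, y0 = self.vertices.min(axis=0)
        x1, y1 = self.vertices.max(axis=0)
        return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


@dataclass
class InstanceMask:
    """Binary raster for one instance; score 1.0 marks ground truth."""

    pixels: np.ndarray
    class_label: str
    score: float = 1.0
    image_id: str = ""
    instance_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixels.any():
            raise ValueError("mask must contain at least one foreground pixel")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# VIA 2.x JSON


def read_via(document, class_attribute: str = "class") -> list:
    """Parse a VIA 2.x project/export into PolygonAnnotations.

    Accepts either the full project form (with ``_via_img_metadata``) or the
    bare metadata map keyed by ``filename+size``. Non-polygon regions are
    skipped with a warning; a polygon region without the class attribute is
    an error naming the region.
    """
    if isinstance(document, (str, bytes)):
        document = json.loads(document)
    metadata = document.get("_via_img_metadata", document)
    annotations = []
    instance = 1
    for key, entry in metadata.items():
        image_id = entry.get("filename", key)
        for ridx, region in enumerate(entry.get("regions", [])):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "polygon":
                log.warning("skipping non-polygon region %d of %s (%s)",
                            ridx, image_id, shape.get("name"))
                continue
            attrs = region.get("region_attributes", {})
            if class_attribute not in attrs:
                raise ValueError(
                    f"region {ridx} of image {image_id!r} lacks the "
                    f"{class_attribute!r} attribute")
            xs, ys = shape["all_points_x"], shape["all_points_y"]
            annotations.append(PolygonAnnotation(
                image_id=image_id, class_label=attrs[class_attribute],
                vertices=np.column_stack([xs, ys]), instance_id=instance))
            instance += 1
    return annotations


def write_via(annotations, image_sizes: dict,
              class_attribute: str = "class") -> dict:
    """Emit a VIA 2.x project document (inverse of :func:`read_via`).

    image_sizes maps image_id -> byte size (0 if unknown; VIA keys entries
    by filename+size).
    """
    metadata = {}
    for ann in annotations:
        size = image_sizes.get(ann.image_id, 0)
        key = f"{ann.image_id}{size}"
        entry = metadata.setdefault(
            key, {"filename": ann.image_id, "size": size, "regions": [],
                  "file_attributes": {}})
        entry["regions"].append({
            "shape_attributes": {
                "name": "polygon",
                "all_points_x": [float(x) for x in ann.vertices[:, 0]],
                "all_points_y": [float(y) for y in ann.vertices[:, 1]],
            },
            "region_attributes": {class_attribute: ann.class_label},
        })
    return {"_via_img_metadata": metadata}


# ---------------------------------------------------------------------------
# COCO-style JSON


def via_to_coco(annotations, image_registry: dict) -> dict:
    """Build a COCO-style document from polygon annotations.

    image_registry maps image_id -> (width, height); every referenced image
    must be registered. Segmentations are flat [x1, y1, x2, y2, ...] lists;
    bbox and area are computed from the polygon (shoelace area via shapely).
    """
    images, image_num = [], {}
    for i, (image_id, (w, h)) in enumerate(sorted(image_registry.items()), 1):
        image_num[image_id] = i
        images.append({"id": i, "file_name": image_id,
                       "width": int(w), "height": int(h)})
    coco_annotations = []
    for i, ann in enumerate(annotations, 1):
        if ann.image_id not in image_num:
            raise ValueError(f"image {ann.image_id!r} not registered")
        if ann.class_label not in CATEGORY_IDS:
            raise ValueError(f"unknown class {ann.class_label!r}")
        coco_annotations.append({
            "id": i,
            "image_id": image_num[ann.image_id],
            "category_id": CATEGORY_IDS[ann.class_label],
            "segmentation": [ann.vertices.ravel().tolist()],
            "bbox": list(ann.bbox),
            "area": float(ann.area),
            "iscrowd": 0,
        })
    categories = [{"id": cid, "name": name}
                  for name, cid in CATEGORY_IDS.items()]
    return {"images": images, "annotations": coco_annotations,
            "categories": categories}


def coco_to_via(document: dict) -> list:
    """Recover PolygonAnnotations from a COCO document written by this module."""
    if isinstance(document, (str, bytes)):
        document = json.loads(document)
    id_to_name = {img["id"]: img["file_name"] for img in document["images"]}
    cat_to_class = {c["id"]: c["name"] for c in document["categories"]}
    out = []
    for ann in document["annotations"]:
        flat = np.asarray(ann["segmentation"][0], dtype=float)
        out.append(PolygonAnnotation(
            image_id=id_to_name[ann["image_id"]],
            class_label=cat_to_class[ann["category_id"]],
            vertices=flat.reshape(-1, 2),
            instance_id=ann["id"]))
    return out


# ---------------------------------------------------------------------------
# per-image normalised polygon text lines (one object per line:
# "class_index x1 y1 x2 y2 ..." with coordinates normalised to [0, 1])


def write_polygon_lines(annotations, width: int, height: int) -> str:
    lines = []
    for ann in annotations:
        idx = CLASS_NAMES.index(ann.class_label)
        coords = ann.vertices / np.array([width, height], dtype=float)
        flat = " ".join(f"{v:.6f}" for v in coords.ravel())
        lines.append(f"{idx} {flat}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_polygon_lines(text: str, width: int, height: int,
                       image_id: str = "") -> list:
    out = []
    for i, line in enumerate(filter(None, map(str.strip, text.splitlines())), 1):
        parts = line.split()
        idx = int(parts[0])
        coords = np.asarray(parts[1:], dtype=float).reshape(-1, 2)
        out.append(PolygonAnnotation(
            image_id=image_id, class_label=CLASS_NAMES[idx],
            vertices=coords * np.array([width, height]), instance_id=i))
    return out


# ---------------------------------------------------------------------------
# rasterisation


def rasterize(annotation: PolygonAnnotation, resolution: tuple) -> InstanceMask:
    """Burn a polygon into a binary raster by the pixel-centre rule.

    A pixel (row r, col c) is foreground iff its centre (c + 0.5, r + 0.5)
    lies inside or on the boundary of the polygon.
    """
    width, height = resolution
    poly = annotation.polygon
    if poly.area <= 0:
        raise ValueError("degenerate polygon has no area")
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx)), width - 1)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy)), height - 1)
    if c1 < c0 or r1 < r0:
        raise ValueError("polygon lies fully outside the raster")
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.intersects_xy(poly, cols + 0.5, rows + 0.5)
    mask = np.zeros((height, width), dtype=bool)
    mask[rows[inside], cols[inside]] = True
    if not mask.any():
        raise ValueError("polygon covers no pixel centres on this raster")
    return InstanceMask(pixels=mask, class_label=annotation.class_label,
                        image_id=annotation.image_id,
                        instance_id=annotation.instance_id)


def trace_outline(mask: InstanceMask) -> PolygonAnnotation:
    """Exact pixel-boundary outline of a mask.

    The outline is the exterior of the union of the unit pixel squares, so
    re-rasterising it reproduces the mask exactly. Interior holes are
    dropped (masks of convex canopy objects have none). Intended for
    compact masks; cost grows with foreground area.
    """
    rows, cols = np.nonzero(mask.pixels)
    squares = [shapely_box(c, r, c + 1, r + 1) for r, c in zip(rows, cols)]
    union = unary_union(squares)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
        warnings.warn("mask has multiple components; tracing the largest")
    verts = np.asarray(union.exterior.coords)[:-1]
    return PolygonAnnotation(image_id=mask.image_id,
                             class_label=mask.class_label,
                             vertices=verts, instance_id=mask.instance_id)


# ---------------------------------------------------------------------------
# tiling


@dataclass
class Tile:
    """One grid tile cut from a larger frame."""

    origin: tuple                 # (x, y) px in the parent frame
    size: tuple                   # (w, h) px; partial trailing tiles smaller
    image: np.ndarray | None
    annotations: list = field(default_factory=list)
    partial: bool = False


def tile_image(image, annotations, tile_w: int = 640, tile_h: int = 540,
               min_visible_area: float = 25.0) -> list:
    """Cut a frame into a non-overlapping grid of tiles from the top-left.

    Polygons are clipped to each tile; clipped pieces with area below
    ``min_visible_area`` (px^2) are dropped; surviving vertices are
    re-expressed in the tile frame. Trailing partial tiles are emitted with
    ``partial=True``.
    """
    image = None if image is None else np.asarray(image)
    if image is not None:
        height, width = image.shape[:2]
    else:
        height = max(int(np.ceil(a.vertices[:, 1].max())) for a in annotations)
        width = max(int(np.ceil(a.vertices[:, 0].max())) for a in annotations)
    if width < tile_w or height < tile_h:
        raise ValueError("image smaller than one tile")

    tiles = []
    for y0 in range(0, height, tile_h):
        for x0 in range(0, width, tile_w):
            w = min(tile_w, width - x0)
            h = min(tile_h, height - y0)
            window = shapely_box(x0, y0, x0 + w, y0 + h)
            sub = None if image is None else image[y0:y0 + h, x0:x0 + w]
            tile = Tile(origin=(x0, y0), size=(w, h), image=sub,
                        partial=(w < tile_w or h < tile_h))
            for ann in annotations:
                clipped = ann.polygon.intersection(window)
                for piece in getattr(clipped, "geoms", [clipped]):
                    if piece.geom_type != "Polygon" or piece.area <= 0 \
                            or piece.area < min_visible_area:
                        continue
                    verts = np.asarray(piece.exterior.coords)[:-1] - (x0, y0)
                    tile.annotations.append(PolygonAnnotation(
                        image_id=f"{ann.image_id}#x{x0}y{y0}",
                        class_label=ann.class_label, vertices=verts,
                        instance_id=ann.instance_id))
            tiles.append(tile)
    return tiles


def instance_masks_from_map(instance_map, class_of_id: dict,
                            image_id: str = "") -> list:
    """Split a per-pixel instance-id raster into InstanceMask objects."""
    out = []
    for iid in np.unique(instance_map):
        if iid == 0 or iid not in class_of_id:
            continue
        out.append(InstanceMask(pixels=instance_map == iid,
                                class_label=class_of_id[iid],
                                image_id=image_id, instance_id=int(iid)))
    return out
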