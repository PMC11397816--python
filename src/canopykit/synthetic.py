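"""Synthetic night-time orchard RGB-D scenes with exact ground truth.

Emulates the imaging geometry of a vehicle-mounted RGB-D camera driven past
mango canopies at night under LED lighting: bright convex fruit (prolate
ellipsoids, long axis hanging vertically), dark irregular branches
(cylinders) and occluding leaves (discs) at 1.5-3 m range, rendered to
640x540 tiles of aligned depth, instance-id and RGB rasters. Every primitive
carries its true pose and dimensions, so fruit sizing, occlusion filtering,
workspace filtering and counting can all be validated against exact ground
truth instead of field data.

Rendering is per-pixel ray casting with a nearest-hit z-buffer using
closed-form ray/quadric intersections. The stored depth is perpendicular
z-depth (rays are parametrised with unit z-component, so the ray parameter
*is* the z-depth). Gaussian depth noise and dropout are applied to the depth
raster only, after geometry; truth records always come from the noiseless
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .camera import CameraIntrinsics, DEFAULT_INTRINSICS


class PrimitiveKind(str, Enum):
    FRUIT_ELLIPSOID = "fruit_ellipsoid"
    BRANCH_CYLINDER = "branch_cylinder"
    LEAF_DISC = "leaf_disc"


_CLASS_OF_KIND = {
    PrimitiveKind.FRUIT_ELLIPSOID: "fruit",
    PrimitiveKind.BRANCH_CYLINDER: "branch",
    PrimitiveKind.LEAF_DISC: "leaf",
}

# Flat shading colours for the RGB render (night scene, LED lighting:
# fruit bright, branches dark, leaves mid-dark, background near-black).
_RGB_OF_CLASS = {"fruit": (210, 185, 90), "branch": (60, 45, 35),
                 "leaf": (40, 70, 35)}
_RGB_BACKGROUND = (8, 8, 12)


@dataclass(frozen=True)
class ScenePrimitive:
    """One shape in the scene, posed in the camera frame (mm).

    dims semantics by kind: ellipsoid -> semi-axes (a, b, c); cylinder ->
    (radius, length); disc -> (radius,). ``rotation`` maps local to camera
    coordinates; the canonical ellipsoid has semi-axis b along local y
    (vertical), the cylinder and disc have their axis along local z.
    """

    kind: PrimitiveKind
    position: np.ndarray
    dims: tuple
    instance_id: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        if any(d <= 0 for d in self.dims):
            raise ValueError("primitive dimensions must be strictly positive")
        if self.instance_id <= 0:
            raise ValueError("instance_id must be positive")

    @property
    def class_label(self) -> str:
        return _CLASS_OF_KIND[self.kind]

    @property
    def long_axis_mm(self) -> float:
        """Fruit length convention: twice the largest semi-axis."""
        if self.kind != PrimitiveKind.FRUIT_ELLIPSOID:
            raise ValueError("long axis defined for fruit ellipsoids only")
        return 2.0 * max(self.dims)

    @property
    def width_mm(self) -> float:
        if self.kind != PrimitiveKind.FRUIT_ELLIPSOID:
            raise ValueError("width defined for fruit ellipsoids only")
        return 2.0 * sorted(self.dims)[1]


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters; defaults emulate the target orchard imagery.

    Fruit lengths ~ Normal(105 mm, 10 mm) truncated to [80, 130] with
    width/length aspect ~ U(0.60, 0.75) (mango fruit are prolate); branch
    radii ~ U(10, 50) mm; camera range ~ U(1500, 3000) mm.
    """

    n_fruit: int = 10
    n_branches: int = 3
    n_leaves: int = 0
    fruit_length_mean: float = 105.0
    fruit_length_sd: float = 10.0
    fruit_length_range: tuple = (80.0, 130.0)
    fruit_aspect_range: tuple = (0.60, 0.75)
    branch_radius_range: tuple = (10.0, 50.0)
    branch_length_mm: float = 2000.0
    leaf_radius_range: tuple = (30.0, 60.0)
    depth_range: tuple = (1500.0, 3000.0)
    occluded_fruit_fraction: float = 0.0   # fraction given a leaf in front
    depth_noise_sd: float = 0.0            # mm, Gaussian, depth only
    dropout_prob: float = 0.0              # depth -> 0 with this probability
    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS

    def validate(self) -> None:
        if min(self.n_fruit, self.n_branches, self.n_leaves) < 0:
            raise ValueError("primitive counts must be non-negative")
        for name in ("fruit_length_range", "fruit_aspect_range",
                     "branch_radius_range", "leaf_radius_range", "depth_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.fruit_length_sd < 0 or self.fruit_length_mean <= 0:
            raise ValueError("fruit length distribution must be positive")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if not (0 <= self.occluded_fruit_fraction <= 1):
            raise ValueError("occluded_fruit_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "intrinsics" in d:
            d["intrinsics"] = CameraIntrinsics(**d["intrinsics"])
        for k in ("fruit_length_range", "fruit_aspect_range", "depth_range",
                  "branch_radius_range", "leaf_radius_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class LabeledScene:
    primitives: tuple
    intrinsics: CameraIntrinsics
    resolution: tuple            # (width, height) px
    seed: int
    depth_noise_sd: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self):
        ids = [p.instance_id for p in self.primitives]
        if len(ids) != len(set(ids)):
            raise ValueError("instance ids must be unique within a scene")
        if min(self.resolution) <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class RenderedFrame:
    """Aligned rasters plus per-instance ground-truth records."""

    depth: np.ndarray          # uint16-compatible float mm, 0 = invalid
    instance_map: np.ndarray   # int32, 0 = background
    rgb: np.ndarray | None
    truth: pd.DataFrame        # indexed by instance_id

    @property
    def resolution(self) -> tuple:
        return (self.depth.shape[1], self.depth.shape[0])


def generate_scene(config: SceneConfig, seed: int) -> LabeledScene:
    """Draw a reproducible scene from the configured distributions.

    Fruit are placed on a jittered angular grid so that fruit do not occlude
    one another; branch cylinders run roughly horizontally across the frame
    at fruit depth or nearer, so they may cross fruit lines of sight; leaves
    are placed deliberately in front of a configured fraction of fruit to
    create partial occlusion, plus any surplus leaves at random.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    K = config.intrinsics
    prims: list[ScenePrimitive] = []
    next_id = 1

    # lateral field of view at the near depth bounds the safe placement grid
    z_near, z_far = config.depth_range
    half_x = 0.85 * (K.width / 2) / K.fx * z_near
    half_y = 0.85 * (K.height / 2) / K.fy * z_near

    n_cells = max(config.n_fruit, 1)
    ncol = int(np.ceil(np.sqrt(n_cells * K.width / K.height)))
    nrow = int(np.ceil(n_cells / ncol))
    cells = [(i, j) for j in range(nrow) for i in range(ncol)]
    rng.shuffle(cells)

    fruit_list: list[ScenePrimitive] = []
    for k in range(config.n_fruit):
        i, j = cells[k % len(cells)]
        cw, ch = 2 * half_x / ncol, 2 * half_y / nrow
        x = -half_x + (i + 0.5) * cw + rng.uniform(-0.15, 0.15) * cw
        y = -half_y + (j + 0.5) * ch + rng.uniform(-0.15, 0.15) * ch
        z = rng.uniform(z_near, z_far)
        length = np.clip(rng.normal(config.fruit_length_mean,
                                    config.fruit_length_sd),
                         *config.fruit_length_range)
        aspect = rng.uniform(*config.fruit_aspect_range)
        b = length / 2.0                 # vertical (long) semi-axis
        a = c = aspect * length / 2.0    # horizontal semi-axes
        fruit_list.append(ScenePrimitive(
            kind=PrimitiveKind.FRUIT_ELLIPSOID, position=(x, y, z),
            dims=(a, b, c), instance_id=next_id))
        next_id += 1
    prims.extend(fruit_list)

    for _ in range(config.n_branches):
        r = rng.uniform(*config.branch_radius_range)
        z = rng.uniform(z_near, 0.5 * (z_near + z_far))
        y = rng.uniform(-half_y, half_y)
        # roughly horizontal axis with mild tilt
        theta = rng.uniform(-0.3, 0.3)
        phi = rng.uniform(-0.2, 0.2)
        axis = np.array([np.cos(theta) * np.cos(phi),
                         np.sin(theta) * np.cos(phi), np.sin(phi)])
        rot = _rotation_to_z(axis)
        prims.append(ScenePrimitive(
            kind=PrimitiveKind.BRANCH_CYLINDER, position=(0.0, y, z),
            dims=(r, config.branch_length_mm), instance_id=next_id,
            rotation=rot))
        next_id += 1

    # deliberate occluders: leaf in front of a fruit, offset to one side so
    # it hides roughly one lateral half of the silhouette
    n_occluded = int(round(config.occluded_fruit_fraction * len(fruit_list)))
    occluded = rng.choice(len(fruit_list), size=n_occluded, replace=False) \
        if n_occluded else []
    for fi in occluded:
        f = fruit_list[fi]
        z_leaf = f.position[2] - rng.uniform(200.0, 400.0)
        scale = z_leaf / f.position[2]
        side = rng.choice([-1.0, 1.0])
        # leaf sized to the fruit silhouette at the leaf depth
        radius = max(f.dims) * scale * rng.uniform(0.9, 1.2)
        offset = np.array([side * f.dims[0] * scale, 0.0, 0.0])
        prims.append(ScenePrimitive(
            kind=PrimitiveKind.LEAF_DISC,
            position=f.position * scale + offset,
            dims=(radius,), instance_id=next_id))
        next_id += 1

    for _ in range(max(0, config.n_leaves - len(occluded))):
        r = rng.uniform(*config.leaf_radius_range)
        z = rng.uniform(z_near, z_far)
        x = rng.uniform(-half_x, half_x)
        y = rng.uniform(-half_y, half_y)
        tilt = _rotation_to_z(_random_unit(rng, max_polar=0.6))
        prims.append(ScenePrimitive(
            kind=PrimitiveKind.LEAF_DISC, position=(x, y, z), dims=(r,),
            instance_id=next_id, rotation=tilt))
        next_id += 1

    return LabeledScene(primitives=tuple(prims), intrinsics=K,
                        resolution=(K.width, K.height), seed=seed,
                        depth_noise_sd=config.depth_noise_sd,
                        dropout_prob=config.dropout_prob)


def _random_unit(rng, max_polar: float) -> np.ndarray:
    az = rng.uniform(0, 2 * np.pi)
    pol = rng.uniform(0, max_polar)
    return np.array([np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az),
                     np.cos(pol)])


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose local +z maps onto ``axis``."""
    z = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 1.0, 0.0]) if abs(z[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# ray casting


def _ray_hit_t(prim: ScenePrimitive, dirs: np.ndarray) -> np.ndarray:
    """Smallest positive ray parameter t (= z-depth, rays have unit z) for
    origin-anchored rays with direction array ``dirs`` of shape (N, 3);
    +inf where the ray misses."""
    R = prim.rotation
    o = -R.T @ prim.position            # camera origin in the local frame
    d = dirs @ R                        # (N, 3) local directions

    if prim.kind == PrimitiveKind.FRUIT_ELLIPSOID:
        inv = 1.0 / np.asarray(prim.dims)
        os, ds = o * inv, d * inv
        A = np.einsum("ij,ij->i", ds, ds)
        B = 2.0 * ds @ os
        C = os @ os - 1.0
        return _smallest_positive_root(A, B, C)

    if prim.kind == PrimitiveKind.BRANCH_CYLINDER:
        radius, length = prim.dims
        A = d[:, 0] ** 2 + d[:, 1] ** 2
        B = 2.0 * (d[:, 0] * o[0] + d[:, 1] * o[1])
        C = o[0] ** 2 + o[1] ** 2 - radius ** 2
        t1, t2 = _quadratic_roots(A, B, C)
        # lateral surface only, clipped to the finite length; the near root
        # may fall outside the span while the far one lands inside it
        best = np.full(len(d), np.inf)
        with np.errstate(invalid="ignore"):
            for t in (t1, t2):
                zhit = o[2] + t * d[:, 2]
                ok = np.isfinite(t) & (t > 1e-9) & (np.abs(zhit) <= length / 2.0)
                best = np.where(ok & (t < best), t, best)
        return best

    if prim.kind == PrimitiveKind.LEAF_DISC:
        (radius,) = prim.dims
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -o[2] / d[:, 2]
        hit = o[:2] + t[:, None] * d[:, :2]
        t = np.where((t > 0) & (np.einsum("ij,ij->i", hit, hit) <= radius ** 2),
                     t, np.inf)
        return t

    raise ValueError(f"unknown primitive kind {prim.kind}")


def _quadratic_roots(A, B, C):
    """Both real roots of A t^2 + B t + C = 0, +inf where complex/degenerate."""
    disc = B ** 2 - 4.0 * A * C
    ok = (disc >= 0) & (A > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, (-B - sq) / (2.0 * A), np.inf)
        t2 = np.where(ok, (-B + sq) / (2.0 * A), np.inf)
    return t1, t2


def _smallest_positive_root(A, B, C):
    t1, t2 = _quadratic_roots(A, B, C)
    return np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, np.inf))


def _ray_directions(K: CameraIntrinsics) -> np.ndarray:
    u, v = np.meshgrid(np.arange(K.width), np.arange(K.height))
    d = np.stack([(u - K.cx) / K.fx, (v - K.cy) / K.fy,
                  np.ones_like(u, dtype=float)], axis=-1)
    return d.reshape(-1, 3)


def _cast(primitives, K: CameraIntrinsics):
    dirs = _ray_directions(K)
    zbuf = np.full(len(dirs), np.inf)
    ids = np.zeros(len(dirs), dtype=np.int32)
    for prim in primitives:
        if prim.position[2] <= 0:
            raise ValueError(f"primitive {prim.instance_id} is behind the camera")
        t = _ray_hit_t(prim, dirs)
        closer = t < zbuf
        zbuf[closer] = t[closer]
        ids[closer] = prim.instance_id
    shape = (K.height, K.width)
    return zbuf.reshape(shape), ids.reshape(shape)


def render(scene: LabeledScene, with_rgb: bool = True) -> RenderedFrame:
    """Ray-cast the scene to depth + instance rasters and truth records.

    Depth noise (Gaussian, sd = scene.depth_noise_sd) and dropout
    (depth -> 0 with prob scene.dropout_prob) are seeded from the scene
    seed and perturb the depth raster only; the instance map and truth
    table always reflect the noiseless geometry. ``occluded_fraction`` per
    fruit compares its visible pixels against a solo re-render.
    """
    K = scene.intrinsics
    zbuf, ids = _cast(scene.primitives, K)
    depth = np.where(np.isfinite(zbuf), zbuf, 0.0)

    records = []
    for prim in scene.primitives:
        visible = int((ids == prim.instance_id).sum())
        rec = {"instance_id": prim.instance_id,
               "class_label": prim.class_label,
               "true_distance_mm": float(prim.position[2]),
               "visible_pixel_count": visible}
        if prim.kind == PrimitiveKind.FRUIT_ELLIPSOID:
            rec["true_length_mm"] = prim.long_axis_mm
            rec["true_width_mm"] = prim.width_mm
            _, solo_ids = _cast([prim], K)
            alone = int((solo_ids == prim.instance_id).sum())
            rec["occluded_fraction"] = (1.0 - visible / alone) if alone else 1.0
        else:
            rec["true_length_mm"] = np.nan
            rec["true_width_mm"] = np.nan
            rec["occluded_fraction"] = np.nan
        records.append(rec)
    truth = pd.DataFrame.from_records(records).set_index("instance_id") \
        if records else pd.DataFrame(
            columns=["class_label", "true_distance_mm", "visible_pixel_count",
                     "true_length_mm", "true_width_mm", "occluded_fraction"])

    noise_rng = np.random.default_rng([scene.seed, 0x5EED])
    if scene.depth_noise_sd > 0:
        valid = depth > 0
        depth = depth + np.where(
            valid, noise_rng.normal(0.0, scene.depth_noise_sd, depth.shape), 0.0)
        depth = np.maximum(depth, 0.0)
    if scene.dropout_prob > 0:
        drop = noise_rng.random(depth.shape) < scene.dropout_prob
        depth = np.where(drop, 0.0, depth)

    rgb = None
    if with_rgb:
        rgb = np.empty((K.height, K.width, 3), dtype=np.uint8)
        rgb[:] = _RGB_BACKGROUND
        for prim in scene.primitives:
            rgb[ids == prim.instance_id] = _RGB_OF_CLASS[prim.class_label]

    return RenderedFrame(depth=depth, instance_map=ids, rgb=rgb, truth=truth)


# ---------------------------------------------------------------------------
# raster I/O (16-bit depth / instance PNGs, 8-bit RGB PNG, truth CSV)


def write_frame(frame: RenderedFrame, out_dir: str | Path,
                prefix: str = "frame") -> dict:
    """Write rasters and the truth table; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"depth": out / f"{prefix}_depth.png",
             "instances": out / f"{prefix}_instances.png",
             "truth": out / f"{prefix}_truth.csv"}
    write_depth_png(frame.depth, paths["depth"])
    write_depth_png(frame.instance_map.astype(np.uint16), paths["instances"])
    frame.truth.to_csv(paths["truth"])
    if frame.rgb is not None:
        paths["rgb"] = out / f"{prefix}_rgb.png"
        Image.fromarray(frame.rgb, mode="RGB").save(paths["rgb"])
    return paths


def write_depth_png(depth_mm, path: str | Path) -> None:
    """Store mm depth as 16-bit single-channel PNG (rounded; 0 = invalid)."""
    arr = np.asarray(depth_mm)
    arr = np.round(arr).clip(0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def read_depth_png(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    return np.asarray(img, dtype=np.uint16)
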