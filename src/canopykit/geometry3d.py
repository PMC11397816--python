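"""Pick-cycle workspace geometry and branch point-cloud filtering.

A harvester arm sweeps a convex 8-vertex prism during each pick cycle: a
rectangular prism when the arm platform is stationary, a trapezoidal prism
when the platform travels vertically while the arm extends (the swept volume
is then taller at the home end than at the fruit). Segmented branch pixels
are back-projected through the depth image into a camera-frame point cloud
and tested for inclusion in the workspace; any branch point inside flags the
pick as obstructed.

Point-in-prism testing uses the half-space parity rule: each face plane is
stored as ax + by + cz + d = 0 with the sign oriented so the prism centroid
evaluates negative, and a point is inside iff it evaluates <= 0 on all six
planes. Boundary points count as inside (conservative for collision
avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .camera import CameraIntrinsics, backproject

_UP = np.array([0.0, -1.0, 0.0])  # camera y points down; "up" is -y


class PickMode(str, Enum):
    STATIONARY = "stationary"  # rectangular prism, height H1 throughout
    MOVING = "moving"          # trapezoidal prism, H2 at home, H1 at fruit


class FilterStrategy(str, Enum):
    RECT_ONLY = "rect_only"
    TRAP_ONLY = "trap_only"
    TRAP_AFTER_RECT = "trap_after_rect"
    RECT_PLUS_TRAP = "rect_plus_trap"


@dataclass(frozen=True)
class PickCycleSpec:
    """Geometry of one pick cycle.

    home/fruit are camera-frame positions (mm) of the gripper palm's home
    and the target fruit; W and H1 are the end-effector width and height;
    H2 is H1 plus the vertical platform travel (moving mode only).
    """

    home: np.ndarray
    fruit: np.ndarray
    width: float
    height1: float
    height2: float | None = None
    mode: PickMode = PickMode.STATIONARY

    def __post_init__(self):
        object.__setattr__(self, "home", np.asarray(self.home, dtype=float))
        object.__setattr__(self, "fruit", np.asarray(self.fruit, dtype=float))
        if self.width <= 0 or self.height1 <= 0:
            raise ValueError("W and H1 must be positive")
        if self.mode == PickMode.MOVING:
            if self.height2 is None:
                raise ValueError("moving mode requires H2")
            if self.height2 < self.height1:
                raise ValueError("H2 must be >= H1")
        if self.fruit[2] <= self.home[2]:
            raise ValueError("fruit must be further from the camera than home")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PickCycleSpec":
        d = yaml.safe_load(Path(path).read_text())
        return cls(home=d["home"], fruit=d["fruit"], width=d["width"],
                   height1=d["height1"], height2=d.get("height2"),
                   mode=PickMode(d.get("mode", "stationary")))


@dataclass(frozen=True)
class PlaneCoefficients:
    """Plane ax + by + cz + d = 0 with normal (a, b, c)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def evaluate(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.normal + self.d


# Face vertex-index quadruples: 0-3 home face (TL, TR, BR, BL as seen from
# the camera), 4-7 fruit face in matching order.
_FACES = (
    (0, 1, 2, 3),  # home face
    (4, 7, 6, 5),  # fruit face
    (0, 1, 5, 4),  # top
    (1, 2, 6, 5),  # right
    (2, 3, 7, 6),  # bottom
    (3, 0, 4, 7),  # left
)


@dataclass(frozen=True)
class Prism:
    """Convex 8-vertex workspace volume with centroid-negative face planes."""

    vertices: np.ndarray                      # (8, 3) mm
    planes: tuple = field(default=())         # 6 PlaneCoefficients
    faces: tuple = _FACES

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def is_axis_aligned_rect(self, tol: float = 1e-9) -> bool:
        """True iff the vertex set spans an axis-aligned rectangular box."""
        lo, hi = self.vertices.min(axis=0), self.vertices.max(axis=0)
        corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                            for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        for c in corners:
            if np.min(np.abs(self.vertices - c).sum(axis=1)) > tol:
                return False
        return True

    def bounds(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


def plane_from_points(A, B, C) -> PlaneCoefficients:
    """Plane through three points, normal = AB x AC (point-normal form)."""
    A = np.asarray(A, dtype=float)
    n = np.cross(np.asarray(B, float) - A, np.asarray(C, float) - A)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(np.asarray(B, float) - A),
                np.linalg.norm(np.asarray(C, float) - A), 1.0)
    if norm <= 1e-12 * scale * scale:
        raise ValueError("collinear points do not define a plane")
    return PlaneCoefficients(a=n[0], b=n[1], c=n[2], d=-float(n @ A))


def _oriented_planes(vertices: np.ndarray, faces=_FACES) -> tuple:
    centroid = vertices.mean(axis=0)
    planes = []
    for quad in faces:
        pl = plane_from_points(*vertices[list(quad[:3])])
        if pl.evaluate(centroid)[0] > 0:
            pl = PlaneCoefficients(-pl.a, -pl.b, -pl.c, -pl.d)
        planes.append(pl)
    return tuple(planes)


def make_workspace(spec: PickCycleSpec) -> Prism:
    """Construct the swept workspace prism for a pick cycle.

    The prism axis runs from home to fruit; the cross-section is W wide
    along the camera-horizontal direction and H tall along camera-vertical
    (-y), with H = H1 at both ends in stationary mode and H2 at the home
    end in moving mode.
    """
    axis = spec.fruit - spec.home
    L = np.linalg.norm(axis)
    if L <= 0:
        raise ValueError("degenerate workspace: home and fruit coincide")
    w = axis / L
    right = np.cross(_UP, w)
    if np.linalg.norm(right) < 1e-12:
        raise ValueError("workspace axis is vertical; horizontal frame undefined")
    right /= np.linalg.norm(right)
    if right[0] < 0:
        right = -right
    up = np.cross(w, right)
    if up @ _UP < 0:
        up = -up

    h_home = spec.height1 if spec.mode == PickMode.STATIONARY else spec.height2
    hw = spec.width / 2.0

    def face(center, hh):
        return [center - hw * right + hh * up,   # top-left
                center + hw * right + hh * up,   # top-right
                center + hw * right - hh * up,   # bottom-right
                center - hw * right - hh * up]   # bottom-left

    vertices = np.array(face(spec.home, h_home / 2.0)
                        + face(spec.fruit, spec.height1 / 2.0))
    return Prism(vertices=vertices, planes=_oriented_planes(vertices))


def point_in_rect_prism(points, prism: Prism, as_printed: bool = False):
    """Axis-aligned rectangular-prism inclusion test.

    Default: min <= coord <= max on all three axes (boundary inside). With
    ``as_printed=True`` the z test degenerates to the one-sided z < max_z
    rule (two-sided non-strict on x and y), reproducing the published
    abridged condition, which admits points nearer than the home plane.
    """
    if not prism.is_axis_aligned_rect():
        raise ValueError("prism is not axis-aligned rectangular; "
                         "use the trapezoidal test (point_in_trap_prism)")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = prism.bounds()
    inside_xy = np.all((p[:, :2] >= lo[:2]) & (p[:, :2] <= hi[:2]), axis=1)
    if as_printed:
        inside_z = p[:, 2] < hi[2]
    else:
        inside_z = (p[:, 2] >= lo[2]) & (p[:, 2] <= hi[2])
    out = inside_xy & inside_z
    return out if np.asarray(points).ndim > 1 else bool(out[0])


def point_in_trap_prism(points, prism: Prism):
    """Half-space parity test: inside iff <= 0 on all centroid-negative planes.

    Tolerance is relative to each plane's normal so prism vertices (exactly
    on two or three faces) land on the inside.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.ones(len(p), dtype=bool)
    for pl in prism.planes:
        tol = 1e-9 * np.linalg.norm(pl.normal) * max(1.0, np.abs(p).max())
        inside &= pl.evaluate(p) <= tol
    return inside if np.asarray(points).ndim > 1 else bool(inside[0])


@dataclass
class PointCloud:
    """Camera-frame points (mm) with per-point source pixel and class."""

    points: np.ndarray                      # (N, 3)
    pixels: np.ndarray | None = None        # (N, 2) source (u, v)
    class_label: str | None = None
    n_invalid_skipped: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def to_ply(self, path: str | Path) -> None:
        cloud = trimesh.PointCloud(self.points)
        Path(path).write_bytes(cloud.export(file_type="ply", encoding="ascii"))

    @classmethod
    def from_ply(cls, path: str | Path) -> "PointCloud":
        cloud = trimesh.load(str(path), file_type="ply")
        return cls(points=np.asarray(cloud.vertices, dtype=float))


def cloud_from_mask(mask, depth_image, K: CameraIntrinsics,
                    class_label: str | None = None) -> PointCloud:
    """Back-project every valid-depth pixel of a binary mask into 3D.

    Pixels whose depth is 0 (no return) are skipped and counted in
    ``n_invalid_skipped``.
    """
    mask = np.asarray(mask, dtype=bool)
    depth = np.asarray(depth_image)
    if mask.shape != depth.shape:
        raise ValueError(f"mask {mask.shape} and depth {depth.shape} "
                         "resolutions differ")
    rows, cols = np.nonzero(mask)
    valid = depth[rows, cols] > 0
    n_skip = int((~valid).sum())
    rows, cols = rows[valid], cols[valid]
    if len(rows) == 0:
        return PointCloud(points=np.empty((0, 3)), pixels=np.empty((0, 2)),
                          class_label=class_label, n_invalid_skipped=n_skip)
    pts = backproject(cols, rows, depth[rows, cols].astype(float), K)
    return PointCloud(points=pts, pixels=np.stack([cols, rows], axis=1),
                      class_label=class_label, n_invalid_skipped=n_skip)


@dataclass
class FilterResult:
    """Partition of a cloud into workspace inside/outside point indices."""

    inside_indices: np.ndarray
    outside_indices: np.ndarray
    obstructed: bool
    mode_used: FilterStrategy
    rect_inside_indices: np.ndarray | None = None  # rect_plus_trap only


def _bounding_rect_prism(prism: Prism) -> Prism:
    lo, hi = prism.bounds()
    v = np.array([
        [lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
        [hi[0], hi[1], lo[2]], [lo[0], hi[1], lo[2]],
        [lo[0], lo[1], hi[2]], [hi[0], lo[1], hi[2]],
        [hi[0], hi[1], hi[2]], [lo[0], hi[1], hi[2]],
    ])
    return Prism(vertices=v, planes=_oriented_planes(v))


def filter_cloud(cloud: PointCloud, spec: PickCycleSpec,
                 strategy: FilterStrategy | str = FilterStrategy.TRAP_AFTER_RECT
                 ) -> FilterResult:
    """Flag branch points inside the pick-cycle workspace.

    Strategies mirror the published filtering variants: ``rect_only`` tests
    the axis-aligned bounding rectangular prism of the workspace (height H2
    in moving mode); ``trap_only`` applies the half-space test to every
    point; ``trap_after_rect`` pre-filters with the cheap bounding-box test
    and applies the half-space test only to survivors (identical inside set
    to trap_only, since the trapezoid is contained in its bounding box);
    ``rect_plus_trap`` reports the trapezoidal inside set and additionally
    the rectangular one.
    """
    strategy = FilterStrategy(strategy)
    prism = make_workspace(spec)
    rect = _bounding_rect_prism(prism)
    pts = cloud.points
    idx = np.arange(len(pts))
    if len(pts) == 0:
        empty = np.empty(0, dtype=int)
        return FilterResult(empty, empty, False, strategy)

    rect_in = point_in_rect_prism(pts, rect)
    if strategy == FilterStrategy.RECT_ONLY:
        inside = rect_in
        rect_report = None
    elif strategy == FilterStrategy.TRAP_ONLY:
        inside = point_in_trap_prism(pts, prism)
        rect_report = None
    elif strategy == FilterStrategy.TRAP_AFTER_RECT:
        inside = np.zeros(len(pts), dtype=bool)
        if rect_in.any():
            inside[rect_in] = point_in_trap_prism(pts[rect_in], prism)
        rect_report = None
    else:  # RECT_PLUS_TRAP
        inside = point_in_trap_prism(pts, prism)
        rect_report = idx[rect_in]
    return FilterResult(inside_indices=idx[inside],
                        outside_indices=idx[~inside],
                        obstructed=bool(inside.any()),
                        mode_used=strategy,
                        rect_inside_indices=rect_report)
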