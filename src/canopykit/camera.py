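"""Pinhole camera model shared by rendering, back-projection and sizing.

Conventions: camera frame is x right, y down, z forward along the optical
axis; all metric quantities are millimetres. Pixel coordinates are 0-based,
(column, row) = (u, v), origin at the top-left pixel centre. Depth images
store perpendicular z-depth (not ray length) with 0 meaning "no return",
matching the 16-bit PNG convention of consumer RGB-D cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixel units.
    cx, cy : float
        Principal point (column, row).
    width, height : int
        Image resolution in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraIntrinsics":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**{k: d[k] for k in ("fx", "fy", "cx", "cy", "width", "height")})


#: Default intrinsics for the synthetic canopy tiles (640x540, ~60 deg HFOV).
DEFAULT_INTRINSICS = CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=270.0,
                                      width=640, height=540)


def backproject(u, v, depth, K: CameraIntrinsics):
    """Map pixel(s) + z-depth (mm) to camera-frame coordinates (mm).

    x = (u - cx) * depth / fx, y = (v - cy) * depth / fy, z = depth.
    Accepts scalars or arrays (broadcast together).
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive (0 encodes invalid)")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u >= K.width) | (v < 0) | (v >= K.height)):
        raise ValueError("pixel coordinates outside the image")
    x = (u - K.cx) * depth / K.fx
    y = (v - K.cy) * depth / K.fy
    return np.stack(np.broadcast_arrays(x, y, depth), axis=-1)


def project(points, K: CameraIntrinsics):
    """Map camera-frame points (mm) to pixel coordinates (u, v)."""
    p = np.asarray(points, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise ValueError("points must be in front of the camera")
    u = p[..., 0] * K.fx / z + K.cx
    v = p[..., 1] * K.fy / z + K.cy
    return np.stack([u, v], axis=-1)
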