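"""RGB-depth sensor-fusion geometry.

The depth camera exposes no intrinsics matrix; each pixel instead carries a
unit ray direction from the calibration look-up table. A depth reading is
the *ray length* in millimeters, so the 3D point for pixel (u, v) with
depth d is ``ray(u, v) * d`` in depth-camera coordinates (not z-depth).
Points are then chained through the rig: depth camera -> rig -> world ->
RGB camera -> RGB image plane, where a standard pinhole projection with
perspective division yields continuous pixel coordinates. Points that land
outside the RGB image (or behind the RGB camera) are dropped; the survivors
form the RGB-depth composite used to lift 2D hand landmarks into 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .formats import DepthFrame, LookUpTable

#: Depth readings below this ray length (meters) are treated as sensor
#: no-return, regardless of the configured validity window.
_MIN_RAY_M = 1e-6

#: Camera-frame z below this (meters) makes perspective division degenerate.
_MIN_PROJ_Z = 1e-6


@dataclass
class PointCloudCamera:
    """Points in depth-camera coordinates, one per retained depth pixel.

    ``pixel_of_origin`` holds the (u=column, v=row) index of each point's
    source pixel; ``depths`` the ray length in meters. Each point's norm
    equals its depth (ray-length convention).
    """

    points: np.ndarray  # (n, 3) meters
    pixel_of_origin: np.ndarray  # (n, 2) int, columns (u, v)
    depths: np.ndarray  # (n,) meters


@dataclass
class PointCloudWorld:
    """Points in world coordinates with their depth-pixel provenance."""

    points: np.ndarray  # (n, 3) meters
    pixel_of_origin: np.ndarray  # (n, 2) int
    depths: np.ndarray  # (n,) meters, source ray length


@dataclass
class RGBDepthComposite:
    """Depth-derived world points paired with their RGB pixel projections.

    Entries are ordered by row-major depth-pixel index, which downstream
    nearest-neighbour queries rely on for deterministic tie-breaking.
    """

    rgb_pixels: np.ndarray  # (n, 2) float, continuous (u, v)
    world_points: np.ndarray  # (n, 3) meters
    depths: np.ndarray  # (n,) meters, source ray length
    pixel_of_origin: np.ndarray  # (n, 2) int
    frame_pair: tuple[int, int] = (-1, -1)  # (rgb_index, depth_index)

    def __len__(self) -> int:
        return len(self.rgb_pixels)


def unproject_depth_frame(
    frame: DepthFrame,
    lut: LookUpTable,
    valid_range: tuple[float, float] = (0.15, 0.45),
) -> PointCloudCamera:
    """Lift a depth image to a depth-camera point cloud via the ray LUT.

    Pixels whose ray length falls outside ``valid_range`` (meters) are
    omitted. Each retained point is ``unit_ray * depth``, so its Euclidean
    norm equals the depth reading.
    """
    values = np.asarray(frame.values)
    if values.shape != lut.shape:
        raise ContractError(
            f"depth frame shape {values.shape} does not match LUT {lut.shape}"
        )
    depth_m = values.astype(float).ravel() * 1e-3
    lo, hi = valid_range
    mask = (depth_m >= max(lo, _MIN_RAY_M)) & (depth_m <= hi)
    idx = np.flatnonzero(mask)  # row-major -> deterministic ordering
    rays = lut.rays.reshape(-1, 3)[idx]
    d = depth_m[idx]
    h, w = lut.shape
    vv, uu = np.divmod(idx, w)
    return PointCloudCamera(
        points=rays * d[:, None],
        pixel_of_origin=np.column_stack([uu, vv]).astype(np.intp),
        depths=d,
    )


def _check_rigid(T: np.ndarray, name: str) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise ContractError(f"{name} must be 4x4")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ContractError(f"{name} is not a proper rigid transform")
    return T


def apply_transform(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (n, 3) point array."""
    points = np.asarray(points, dtype=float)
    return points @ T[:3, :3].T + T[:3, 3]


def camera_to_world(
    cloud: PointCloudCamera,
    rig2cam_depth: np.ndarray,
    rig2world_depth: np.ndarray,
) -> PointCloudWorld:
    """Map depth-camera points to world coordinates.

    The chain is ``rig2world_depth @ inv(rig2cam_depth)`` applied in
    homogeneous coordinates: camera -> rig -> world.
    """
    rig2cam = _check_rigid(rig2cam_depth, "rig2cam_depth")
    rig2world = _check_rigid(rig2world_depth, "rig2world_depth")
    cam2rig = invert_rigid(rig2cam)
    T = rig2world @ cam2rig
    return PointCloudWorld(
        points=apply_transform(T, cloud.points),
        pixel_of_origin=cloud.pixel_of_origin,
        depths=cloud.depths,
    )


def invert_rigid(T: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a rigid 4x4 transform."""
    R = T[:3, :3]
    t = T[:3, 3]
    inv = np.eye(4)
    inv[:3, :3] = R.T
    inv[:3, 3] = -R.T @ t
    return inv


def project_world_to_rgb(
    cloud: PointCloudWorld,
    cam2world_rgb: np.ndarray,
    K_rgb: np.ndarray,
    rgb_size: tuple[int, int],
    frame_pair: tuple[int, int] = (-1, -1),
) -> RGBDepthComposite:
    """Project world points into the RGB image to form the composite.

    World points are taken to RGB-camera coordinates with the inverse of
    the camera pose, then through the pinhole intrinsics with perspective
    division by the camera-frame z. Points behind the camera or outside
    ``[0, w) x [0, h)`` are removed. An empty composite is returned (with
    a warning) when nothing survives.
    """
    if len(cloud.points) == 0:
        raise ContractError("cannot project an empty point cloud")
    cam2world = _check_rigid(cam2world_rgb, "cam2world_rgb")
    K = np.asarray(K_rgb, dtype=float)
    w, h = rgb_size

    p_cam = apply_transform(invert_rigid(cam2world), cloud.points)
    z = p_cam[:, 2]
    front = z > _MIN_PROJ_Z
    uvz = p_cam[front] @ K.T
    uv = uvz[:, :2] / uvz[:, 2:3]
    in_frame = (
        (uv[:, 0] >= 0.0) & (uv[:, 0] < w) & (uv[:, 1] >= 0.0) & (uv[:, 1] < h)
    )
    keep_front = np.flatnonzero(front)[in_frame]
    if keep_front.size == 0:
        warnings.warn(
            "no depth points project into the RGB frame; empty composite",
            RuntimeWarning,
            stacklevel=2,
        )
    return RGBDepthComposite(
        rgb_pixels=uv[in_frame],
        world_points=cloud.points[keep_front],
        depths=cloud.depths[keep_front],
        pixel_of_origin=cloud.pixel_of_origin[keep_front],
        frame_pair=frame_pair,
    )


def build_composite(
    frame: DepthFrame,
    rig,
    depth_index: int,
    rgb_index: int,
    valid_range: tuple[float, float] = (0.15, 0.45),
) -> RGBDepthComposite:
    """Full depth-frame -> composite chain for one RGB/depth frame pair."""
    cloud_cam = unproject_depth_frame(frame, rig.lut, valid_range=valid_range)
    if len(cloud_cam.points) == 0:
        return RGBDepthComposite(
            rgb_pixels=np.zeros((0, 2)),
            world_points=np.zeros((0, 3)),
            depths=np.zeros(0),
            pixel_of_origin=np.zeros((0, 2), dtype=np.intp),
            frame_pair=(rgb_index, depth_index),
        )
    cloud_world = camera_to_world(
        cloud_cam, rig.rig2cam_depth, rig.rig2world_depth[depth_index]
    )
    return project_world_to_rgb(
        cloud_world,
        rig.cam2world_rgb[rgb_index],
        rig.K_rgb,
        rig.rgb_size,
        frame_pair=(rgb_index, depth_index),
    )
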