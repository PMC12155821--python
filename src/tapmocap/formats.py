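"""Readers and writers for the capture-bundle dialects.

A capture bundle mirrors what a head-worn RGB-depth device exports in
research mode:

* ``depth.tar`` — one binary PGM (``P5``, maxval 65535, big-endian) per
  depth frame, 512x512, values in millimeters (ray length).
* ``rgb.tar`` — one header-free raw-byte member per RGB frame, row-major
  8-bit interleaved RGB (a planar variant is selectable), 640x360.
* ``calibration/`` — whitespace-delimited text files: the RGB intrinsics
  ``K_RGB.txt``, per-frame ``Cam2World_RGB.txt`` and ``Rig2World_Depth.txt``
  transform stacks (4 lines per 4x4 block), the single ``Rig2Cam_Depth.txt``
  transform, the per-pixel ray ``LUT.txt``, both timestamp lists, and the
  RGB image size.

The device does not expose depth intrinsics; instead the look-up table
(LUT) stores, for every depth pixel, the unit ray direction in depth-camera
coordinates. Rays are normalized at load time so downstream geometry can
rely on the ray-length depth convention.

All timestamps are seconds as floats, zeroed to the first RGB frame at
calibration load time.
"""

from __future__ import annotations

import io
import re
import tarfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, FormatError, SchemaError

DEPTH_SHAPE = (512, 512)
RGB_SIZE = (640, 360)  # (width, height)
N_LANDMARKS = 21

_K_RGB_FILE = "K_RGB.txt"
_CAM2WORLD_RGB_FILE = "Cam2World_RGB.txt"
_RIG2CAM_DEPTH_FILE = "Rig2Cam_Depth.txt"
_RIG2WORLD_DEPTH_FILE = "Rig2World_Depth.txt"
_LUT_FILE = "LUT.txt"
_TS_RGB_FILE = "Timestamps_RGB.txt"
_TS_DEPTH_FILE = "Timestamps_Depth.txt"
_RGB_SIZE_FILE = "RGB_Size.txt"


@dataclass
class DepthFrame:
    """One depth image: 512x512 integer millimeter ray lengths."""

    timestamp: float
    values: np.ndarray  # (512, 512) uint16, mm
    frame_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != DEPTH_SHAPE:
            raise FormatError(
                f"depth frame shape {self.values.shape}, expected {DEPTH_SHAPE}"
            )
        if self.values.min() < 0:
            raise FormatError("depth values must be non-negative")


@dataclass
class RGBFrame:
    """One RGB image, 640x360x3 uint8."""

    timestamp: float
    pixels: np.ndarray  # (height, width, 3) uint8
    frame_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        w, h = RGB_SIZE
        if self.pixels.shape != (h, w, 3):
            raise FormatError(
                f"RGB frame shape {self.pixels.shape}, expected {(h, w, 3)}"
            )


@dataclass
class LookUpTable:
    """Per-depth-pixel unit ray directions in depth-camera coordinates."""

    rays: np.ndarray  # (H, W, 3), unit length, z > 0

    def __post_init__(self) -> None:
        self.rays = np.asarray(self.rays, dtype=float)
        if self.rays.ndim != 3 or self.rays.shape[2] != 3:
            raise CalibrationError(f"LUT shape {self.rays.shape}, expected (H, W, 3)")
        if np.any(self.rays[..., 2] <= 0):
            raise CalibrationError("LUT rays must have positive z component")
        norms = np.linalg.norm(self.rays, axis=2, keepdims=True)
        if np.any(norms == 0):
            raise CalibrationError("LUT contains a zero ray")
        self.rays = self.rays / norms

    @property
    def shape(self) -> tuple[int, int]:
        return self.rays.shape[:2]


@dataclass
class CameraRig:
    """Calibration state of the RGB + depth rig.

    ``cam2world_rgb`` and ``rig2world_depth`` are per-frame 4x4 rigid
    transform stacks; ``rig2cam_depth`` is a single rigid transform.
    Timestamps are seconds, zeroed to the first RGB frame.
    """

    K_rgb: np.ndarray  # (3, 3)
    cam2world_rgb: np.ndarray  # (n_rgb, 4, 4)
    rig2cam_depth: np.ndarray  # (4, 4)
    rig2world_depth: np.ndarray  # (n_depth, 4, 4)
    lut: LookUpTable
    rgb_size: tuple[int, int] = RGB_SIZE
    timestamps_rgb: np.ndarray = field(default_factory=lambda: np.zeros(0))
    timestamps_depth: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.K_rgb = np.asarray(self.K_rgb, dtype=float)
        if self.K_rgb.shape != (3, 3):
            raise CalibrationError("K_rgb must be 3x3")
        if not np.allclose(self.K_rgb[2], [0.0, 0.0, 1.0]) or np.any(
            self.K_rgb[1:, 0] != 0.0
        ):
            raise CalibrationError("K_rgb must be an upper-triangular pinhole matrix")
        self.cam2world_rgb = _as_transform_stack(self.cam2world_rgb, "Cam2World_RGB")
        self.rig2world_depth = _as_transform_stack(
            self.rig2world_depth, "Rig2World_Depth"
        )
        self.rig2cam_depth = _as_transform_stack(
            np.asarray(self.rig2cam_depth)[None], "Rig2Cam_Depth"
        )[0]
        self.timestamps_rgb = np.asarray(self.timestamps_rgb, dtype=float)
        self.timestamps_depth = np.asarray(self.timestamps_depth, dtype=float)


@dataclass
class MarkerTrajectory:
    """Named 3D marker tracks from a reference motion-capture system.

    Positions are centimeters; timestamps seconds at ``source_rate``.
    """

    timestamps: np.ndarray
    positions: dict[str, np.ndarray]  # name -> (n, 3) cm
    source_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise SchemaError("marker timestamps must be strictly increasing")
        n = len(self.timestamps)
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise SchemaError(f"marker {name!r} has shape {pos.shape}, expected ({n}, 3)")
            self.positions[name] = pos


def _as_transform_stack(stack: np.ndarray, name: str) -> np.ndarray:
    """Validate a (n, 4, 4) stack of rigid transforms."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[1:] != (4, 4):
        raise CalibrationError(f"{name} must be a stack of 4x4 matrices")
    R = stack[:, :3, :3]
    should_eye = np.einsum("nij,nkj->nik", R, R)
    if not np.allclose(should_eye, np.eye(3), atol=1e-6):
        raise CalibrationError(f"{name} rotation block is not orthonormal")
    if np.any(np.linalg.det(R) < 0):
        raise CalibrationError(f"{name} rotation block has determinant -1 (reflection)")
    if not np.allclose(stack[:, 3], [0.0, 0.0, 0.0, 1.0]):
        raise CalibrationError(f"{name} bottom row must be (0, 0, 0, 1)")
    return stack


# ---------------------------------------------------------------------------
# PGM depth archives


def _parse_pgm(data: bytes, member: str) -> np.ndarray:
    """Parse a binary PGM (P5). Only maxval 65535 (16-bit depth) is accepted."""
    tokens: list[bytes] = []
    pos = 0
    while len(tokens) < 4:
        m = re.match(rb"\s*(?:#[^\n]*\n\s*)*(\S+)", data[pos:])
        if m is None:
            raise FormatError(f"{member}: truncated PGM header")
        tokens.append(m.group(1))
        pos += m.end()
    magic, w_s, h_s, maxval_s = tokens
    if magic != b"P5":
        raise FormatError(f"{member}: not a binary PGM (magic {magic!r})")
    try:
        w, h, maxval = int(w_s), int(h_s), int(maxval_s)
    except ValueError as exc:
        raise FormatError(f"{member}: malformed PGM header") from exc
    if maxval != 65535:
        raise FormatError(f"{member}: PGM maxval {maxval}, expected 65535 (16-bit depth)")
    pos += 1  # single whitespace after maxval
    raster = data[pos:]
    expected = w * h * 2
    if len(raster) != expected:
        raise FormatError(
            f"{member}: raster size {len(raster)} bytes, expected {expected}"
        )
    return np.frombuffer(raster, dtype=">u2").reshape(h, w).astype(np.uint16)


def _encode_pgm(values: np.ndarray) -> bytes:
    h, w = values.shape
    header = f"P5\n{w} {h}\n65535\n".encode()
    return header + values.astype(">u2").tobytes()


def _member_index(name: str) -> int:
    """Frame ordinal from a member name; archives index members by name."""
    m = re.search(r"(\d+)\D*$", name)
    if m is None:
        raise FormatError(f"archive member {name!r} carries no frame index")
    return int(m.group(1))


def _load_timestamps(timestamps: "str | Path | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(timestamps, (str, Path)):
        ts = np.loadtxt(timestamps, dtype=float, ndmin=1)
    else:
        ts = np.asarray(timestamps, dtype=float)
    if ts.ndim != 1:
        raise FormatError("timestamp list must be one-dimensional")
    if np.any(np.diff(ts) <= 0):
        raise FormatError("timestamps must be strictly increasing")
    return ts


def read_depth_archive(
    path: str | Path,
    timestamps: "str | Path | Sequence[float] | np.ndarray",
) -> list[DepthFrame]:
    """Read a tar archive of PGM depth frames.

    ``timestamps`` is the accompanying per-frame timestamp list (file path
    or array); its length must match the archive. Frames are returned
    sorted by timestamp regardless of archive member order.
    """
    ts = _load_timestamps(timestamps)
    frames: list[tuple[int, np.ndarray]] = []
    with tarfile.open(path, "r") as tf:
        for member in tf.getmembers():
            if not member.isfile():
                continue
            data = tf.extractfile(member).read()
            frames.append((_member_index(member.name), _parse_pgm(data, member.name)))
    if len(frames) != len(ts):
        raise FormatError(
            f"depth archive has {len(frames)} frames but {len(ts)} timestamps"
        )
    frames.sort(key=lambda item: ts[item[0]])
    return [
        DepthFrame(timestamp=float(ts[idx]), values=vals, frame_index=idx)
        for idx, vals in frames
    ]


def write_depth_archive(
    path: str | Path, frames: Iterable[np.ndarray | DepthFrame]
) -> None:
    """Write depth frames as ``depth_NNNNNN.pgm`` members of a tar archive."""
    with tarfile.open(path, "w") as tf:
        for i, frame in enumerate(frames):
            values = frame.values if isinstance(frame, DepthFrame) else np.asarray(frame)
            payload = _encode_pgm(values)
            info = tarfile.TarInfo(name=f"depth_{i:06d}.pgm")
            info.size = len(payload)
            tf.addfile(info, io.BytesIO(payload))


# ---------------------------------------------------------------------------
# Raw-byte RGB archives


def read_rgb_archive(
    path: str | Path,
    timestamps: "str | Path | Sequence[float] | np.ndarray",
    rgb_size: tuple[int, int] = RGB_SIZE,
    planar: bool = False,
) -> list[RGBFrame]:
    """Read a tar archive of header-free raw RGB byte members.

    Each member must be exactly ``width*height*3`` bytes. The default pixel
    layout is row-major channel-interleaved; ``planar`` selects the
    RRR..GGG..BBB variant.
    """
    ts = _load_timestamps(timestamps)
    w, h = rgb_size
    expected = w * h * 3
    frames: list[tuple[int, np.ndarray]] = []
    with tarfile.open(path, "r") as tf:
        for member in tf.getmembers():
            if not member.isfile():
                continue
            data = tf.extractfile(member).read()
            if len(data) != expected:
                raise FormatError(
                    f"{member.name}: {len(data)} bytes, expected {expected} "
                    f"for {w}x{h}x3"
                )
            buf = np.frombuffer(data, dtype=np.uint8)
            pixels = buf.reshape(3, h, w).transpose(1, 2, 0) if planar else buf.reshape(h, w, 3)
            frames.append((_member_index(member.name), pixels))
    if len(frames) != len(ts):
        raise FormatError(f"RGB archive has {len(frames)} frames but {len(ts)} timestamps")
    frames.sort(key=lambda item: ts[item[0]])
    return [
        RGBFrame(timestamp=float(ts[idx]), pixels=px, frame_index=idx)
        for idx, px in frames
    ]


def write_rgb_archive(
    path: str | Path, frames: Iterable[np.ndarray], planar: bool = False
) -> None:
    """Write RGB frames as raw-byte ``rgb_NNNNNN.bin`` members."""
    with tarfile.open(path, "w") as tf:
        for i, pixels in enumerate(frames):
            arr = np.ascontiguousarray(np.asarray(pixels, dtype=np.uint8))
            if planar:
                arr = np.ascontiguousarray(arr.transpose(2, 0, 1))
            payload = arr.tobytes()
            info = tarfile.TarInfo(name=f"rgb_{i:06d}.bin")
            info.size = len(payload)
            tf.addfile(info, io.BytesIO(payload))


# ---------------------------------------------------------------------------
# Camera-parameter text files


def read_rig_calibration(param_dir: str | Path) -> CameraRig:
    """Read the camera-parameter text files of a capture bundle.

    LUT rays are normalized to unit length at load. Both timestamp lists
    are zeroed to the first RGB timestamp.
    """
    d = Path(param_dir)
    for fname in (
        _K_RGB_FILE,
        _CAM2WORLD_RGB_FILE,
        _RIG2CAM_DEPTH_FILE,
        _RIG2WORLD_DEPTH_FILE,
        _LUT_FILE,
        _TS_RGB_FILE,
        _TS_DEPTH_FILE,
    ):
        if not (d / fname).is_file():
            raise CalibrationError(f"missing calibration file {fname}")

    K = np.loadtxt(d / _K_RGB_FILE)
    ts_rgb = np.loadtxt(d / _TS_RGB_FILE, ndmin=1)
    ts_depth = np.loadtxt(d / _TS_DEPTH_FILE, ndmin=1)
    t0 = float(ts_rgb[0])
    cam2world = _read_transform_stack(d / _CAM2WORLD_RGB_FILE)
    rig2cam = _read_transform_stack(d / _RIG2CAM_DEPTH_FILE)
    if rig2cam.shape[0] != 1:
        raise CalibrationError("Rig2Cam_Depth must contain exactly one transform")
    rig2world = _read_transform_stack(d / _RIG2WORLD_DEPTH_FILE)
    if cam2world.shape[0] != len(ts_rgb):
        raise CalibrationError(
            f"{cam2world.shape[0]} RGB poses for {len(ts_rgb)} RGB timestamps"
        )
    if rig2world.shape[0] != len(ts_depth):
        raise CalibrationError(
            f"{rig2world.shape[0]} depth poses for {len(ts_depth)} depth timestamps"
        )

    with open(d / _LUT_FILE) as fh:
        dims = fh.readline().split()
        if len(dims) != 2:
            raise CalibrationError("LUT file must start with 'height width'")
        lut_h, lut_w = int(dims[0]), int(dims[1])
        flat = np.loadtxt(fh)
    if flat.shape != (lut_h * lut_w, 3):
        raise CalibrationError(
            f"LUT body has shape {flat.shape}, expected ({lut_h * lut_w}, 3)"
        )
    lut = LookUpTable(rays=flat.reshape(lut_h, lut_w, 3))

    rgb_size = RGB_SIZE
    if (d / _RGB_SIZE_FILE).is_file():
        w, h = np.loadtxt(d / _RGB_SIZE_FILE, dtype=int)
        rgb_size = (int(w), int(h))

    return CameraRig(
        K_rgb=K,
        cam2world_rgb=cam2world,
        rig2cam_depth=rig2cam[0],
        rig2world_depth=rig2world,
        lut=lut,
        rgb_size=rgb_size,
        timestamps_rgb=ts_rgb - t0,
        timestamps_depth=ts_depth - t0,
    )


def write_rig_calibration(param_dir: str | Path, rig: CameraRig) -> None:
    """Write a :class:`CameraRig` in the text dialect read back by
    :func:`read_rig_calibration`."""
    d = Path(param_dir)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / _K_RGB_FILE, rig.K_rgb, fmt="%.12g")
    _write_transform_stack(d / _CAM2WORLD_RGB_FILE, rig.cam2world_rgb)
    _write_transform_stack(d / _RIG2CAM_DEPTH_FILE, rig.rig2cam_depth[None])
    _write_transform_stack(d / _RIG2WORLD_DEPTH_FILE, rig.rig2world_depth)
    h, w = rig.lut.shape
    with open(d / _LUT_FILE, "w") as fh:
        fh.write(f"{h} {w}\n")
        np.savetxt(fh, rig.lut.rays.reshape(-1, 3), fmt="%.9g")
    np.savetxt(d / _TS_RGB_FILE, rig.timestamps_rgb, fmt="%.12f")
    np.savetxt(d / _TS_DEPTH_FILE, rig.timestamps_depth, fmt="%.12f")
    np.savetxt(d / _RGB_SIZE_FILE, np.asarray(rig.rgb_size)[None], fmt="%d")


def _read_transform_stack(path: Path) -> np.ndarray:
    flat = np.loadtxt(path)
    if flat.ndim == 1:
        flat = flat[None]
    if flat.shape[1] != 4 or flat.shape[0] % 4 != 0:
        raise CalibrationError(f"{path.name}: expected blocks of 4x4 rows")
    stack = flat.reshape(-1, 4, 4)
    return _as_transform_stack(stack, path.name)


def _write_transform_stack(path: Path, stack: np.ndarray) -> None:
    np.savetxt(path, np.asarray(stack).reshape(-1, 4), fmt="%.15g")


# ---------------------------------------------------------------------------
# Landmark and marker tables


def write_landmark_table(traj, path: str | Path) -> None:
    """Write a hand trajectory as CSV: timestamp, 21x(x, y, z) world
    coordinates in meters, validity and interpolation flags, hand label."""
    n = len(traj.timestamps)
    if n == 0:
        raise ValueError("cannot write an empty trajectory")
    cols: dict[str, np.ndarray] = {"timestamp": np.asarray(traj.timestamps, dtype=float)}
    lm = np.asarray(traj.landmarks, dtype=float)
    for i in range(N_LANDMARKS):
        for j, ax in enumerate("xyz"):
            cols[f"lm{i:02d}_{ax}"] = lm[:, i, j]
    cols["valid"] = np.asarray(traj.valid, dtype=int)
    cols["interpolated"] = np.asarray(traj.interpolated, dtype=int)
    cols["hand"] = np.full(n, traj.hand_label)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_landmark_table(path: str | Path):
    """Read a landmark CSV written by :func:`write_landmark_table`."""
    from .reconstruct import HandTrajectory  # local import; avoids a cycle

    df = pd.read_csv(path)
    needed = {"timestamp", "valid", "interpolated", "hand"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"landmark table missing columns {sorted(missing)}")
    lm = np.empty((len(df), N_LANDMARKS, 3))
    for i in range(N_LANDMARKS):
        for j, ax in enumerate("xyz"):
            col = f"lm{i:02d}_{ax}"
            if col not in df.columns:
                raise SchemaError(f"landmark table missing column {col}")
            lm[:, i, j] = df[col].to_numpy()
    return HandTrajectory(
        timestamps=df["timestamp"].to_numpy(dtype=float),
        landmarks=lm,
        valid=df["valid"].to_numpy(dtype=bool),
        interpolated=df["interpolated"].to_numpy(dtype=bool),
        hand_label=str(df["hand"].iloc[0]),
    )


def read_reference_markers(
    path: str | Path,
    required: Sequence[str] = ("thumb_tip", "index_tip"),
) -> MarkerTrajectory:
    """Read a reference motion-capture marker CSV.

    Expected columns: ``timestamp`` plus ``<marker>_x/_y/_z`` triplets in
    centimeters. ``required`` markers must be present.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise SchemaError("marker CSV must have a 'timestamp' column")
    names = sorted(
        {c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))}
    )
    names = [
        m for m in names if all(f"{m}_{ax}" in df.columns for ax in "xyz")
    ]
    for marker in required:
        if marker not in names:
            raise SchemaError(f"marker CSV missing required marker {marker!r}")
    ts = df["timestamp"].to_numpy(dtype=float)
    positions = {
        m: df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy(dtype=float) for m in names
    }
    dt = np.diff(ts)
    rate = 1.0 / float(np.median(dt)) if len(dt) else float("nan")
    return MarkerTrajectory(timestamps=ts, positions=positions, source_rate=rate)


def write_reference_markers(path: str | Path, traj: MarkerTrajectory) -> None:
    """Write a :class:`MarkerTrajectory` as a marker CSV (centimeters)."""
    cols: dict[str, np.ndarray] = {"timestamp": traj.timestamps}
    for name, pos in traj.positions.items():
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = pos[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
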