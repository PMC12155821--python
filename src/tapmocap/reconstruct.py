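"""3D hand-landmark reconstruction from paired RGB and depth frames.

Each RGB frame is paired with the temporally closest depth frame; a
pluggable 2D detector supplies 21 normalized hand-landmark coordinates
which are converted to pixels, matched to the nearest entry of the
RGB-depth composite, and replaced by that entry's world point. Samples
failing any validity rule (missing depth frame, out-of-range depth,
detection failure) are linearly interpolated from their valid neighbours.

The detector is an adapter: any callable/object with
``detect(pixels) -> (21, 2) normalized coords or None`` fits, so a neural
hand-landmark model and the synthetic rig's oracle detector are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import ContractError, QualityError
from .formats import N_LANDMARKS, RGBFrame, read_depth_archive, read_rig_calibration
from .geometry import RGBDepthComposite, build_composite

#: Landmark indices of the two tips the tapping metrics use (the standard
#: 21-point hand topology: 4 = thumb tip, 8 = index fingertip).
THUMB_TIP = 4
INDEX_TIP = 8


class LandmarkDetector(Protocol):
    """Adapter contract for 2D hand-landmark detectors."""

    def detect(self, pixels: np.ndarray) -> np.ndarray | None:
        """Return (21, 2) normalized [0, 1] landmark coords, or None."""
        ...


@dataclass
class LandmarkSet2D:
    """21 detected 2D landmarks for one RGB frame (normalized + pixels)."""

    rgb_frame_index: int
    coords_norm: np.ndarray | None  # (21, 2) in [0, 1], None if undetected
    coords_px: np.ndarray | None  # (21, 2) pixels
    detected: bool


@dataclass
class FramePairing:
    """An RGB frame matched to its temporally nearest depth frame."""

    rgb_index: int
    depth_index: int
    offset: float  # |t_rgb - t_depth|, seconds
    missing_depth: bool  # offset exceeded the pairing threshold


@dataclass
class HandTrajectory:
    """Time series of 21 world-space hand landmarks for one hand-trial."""

    timestamps: np.ndarray  # seconds, RGB clock
    landmarks: np.ndarray  # (n, 21, 3) meters
    valid: np.ndarray  # (n,) bool
    interpolated: np.ndarray = field(default=None)  # (n,) bool
    hand_label: str = "right"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.timestamps), dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ContractError("trajectory timestamps must be strictly increasing")
        if self.landmarks.shape != (len(self.timestamps), N_LANDMARKS, 3):
            raise ContractError(
                f"landmarks shape {self.landmarks.shape}, expected "
                f"({len(self.timestamps)}, {N_LANDMARKS}, 3)"
            )


def pairing_threshold(ts_depth: Sequence[float]) -> float:
    """Half the depth sampling period — the worst-case RGB-depth offset.

    At the device's 45 Hz depth rate this is 1/(2*45) ≈ 11.1 ms; any
    larger offset implies a dropped depth frame.
    """
    dt = np.diff(np.asarray(ts_depth, dtype=float))
    if len(dt) == 0:
        raise ContractError("need at least two depth timestamps")
    return float(np.median(dt)) / 2.0


def pair_frames(
    ts_rgb: Sequence[float],
    ts_depth: Sequence[float],
    threshold: float | None = None,
) -> list[FramePairing]:
    """Match every RGB frame to its nearest depth frame in time.

    ``threshold`` defaults to half the (median) depth period; pairings
    whose offset exceeds it are flagged ``missing_depth`` and later
    interpolated rather than lifted.
    """
    ts_rgb = np.asarray(ts_rgb, dtype=float)
    ts_depth = np.asarray(ts_depth, dtype=float)
    if ts_rgb.size == 0 or ts_depth.size == 0:
        raise ContractError("both timestamp lists must be non-empty")
    if threshold is None:
        threshold = pairing_threshold(ts_depth) if ts_depth.size > 1 else np.inf

    pos = np.searchsorted(ts_depth, ts_rgb)
    left = np.clip(pos - 1, 0, len(ts_depth) - 1)
    right = np.clip(pos, 0, len(ts_depth) - 1)
    pick_right = np.abs(ts_depth[right] - ts_rgb) < np.abs(ts_depth[left] - ts_rgb)
    nearest = np.where(pick_right, right, left)
    offsets = np.abs(ts_depth[nearest] - ts_rgb)
    # threshold comparison padded by float epsilon so the exact boundary
    # offset (e.g. 11.1 ms at 45 Hz) still counts as paired
    return [
        FramePairing(
            rgb_index=i,
            depth_index=int(nearest[i]),
            offset=float(offsets[i]),
            missing_depth=bool(offsets[i] > threshold * (1 + 1e-9)),
        )
        for i in range(len(ts_rgb))
    ]


def detect_landmarks_2d(
    frame: RGBFrame,
    detector: LandmarkDetector,
    rgb_size: tuple[int, int] | None = None,
) -> LandmarkSet2D:
    """Run the detector adapter on one RGB frame.

    Normalized coordinates are scaled by the image width/height to pixel
    coordinates. A detector returning no hand yields ``detected=False``.
    """
    result = detector.detect(frame.pixels)
    if result is None:
        return LandmarkSet2D(
            rgb_frame_index=frame.frame_index,
            coords_norm=None,
            coords_px=None,
            detected=False,
        )
    coords = np.asarray(result, dtype=float)
    if coords.shape != (N_LANDMARKS, 2):
        raise ContractError(
            f"detector returned shape {coords.shape}, expected ({N_LANDMARKS}, 2)"
        )
    if rgb_size is None:
        h, w = frame.pixels.shape[:2]
    else:
        w, h = rgb_size
    return LandmarkSet2D(
        rgb_frame_index=frame.frame_index,
        coords_norm=coords,
        coords_px=coords * np.array([w, h], dtype=float),
        detected=True,
    )


def lift_landmarks(
    lm: LandmarkSet2D, composite: RGBDepthComposite
) -> tuple[np.ndarray, np.ndarray]:
    """Lift 2D landmarks to world points via the RGB-depth composite.

    For each landmark pixel the composite entry with minimum 2D Euclidean
    pixel distance is selected; ties resolve to the lowest row-major
    depth-pixel index (composite entries are stored in that order, and
    ``argmin`` returns the first minimum). Returns (21, 3) world points
    and the (21,) ray-length depths of the selected entries.
    """
    if not lm.detected or lm.coords_px is None:
        raise ContractError("cannot lift an undetected landmark set")
    if len(composite) == 0:
        raise ContractError("cannot lift landmarks with an empty composite")
    # (21, n) squared pixel distances; n is modest (hand-sized point sets)
    d2 = (
        (lm.coords_px[:, None, :] - composite.rgb_pixels[None, :, :]) ** 2
    ).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    return composite.world_points[nearest], composite.depths[nearest]


def validate_and_interpolate(
    traj: HandTrajectory,
    pairings: Sequence[FramePairing] | None = None,
    landmark_depths: np.ndarray | None = None,
    detected: np.ndarray | None = None,
    depth_valid_m: tuple[float, float] = (0.15, 0.45),
) -> HandTrajectory:
    """Apply the per-sample validity rules and fill gaps by interpolation.

    A sample is invalid when its pairing was flagged missing-depth, any
    of its lifted depths lies outside ``depth_valid_m``, or detection
    failed. Invalid samples are replaced by per-coordinate linear
    interpolation between the nearest valid neighbours; leading/trailing
    gaps hold the nearest valid sample. Raises :class:`QualityError` when
    no valid sample remains.
    """
    n = len(traj.timestamps)
    valid = np.asarray(traj.valid, dtype=bool).copy()
    if pairings is not None:
        if len(pairings) != n:
            raise ContractError("pairings and trajectory must be aligned by rgb index")
        valid &= ~np.array([p.missing_depth for p in pairings], dtype=bool)
    if detected is not None:
        valid &= np.asarray(detected, dtype=bool)
    if landmark_depths is not None:
        depths = np.asarray(landmark_depths, dtype=float)
        lo, hi = depth_valid_m
        valid &= np.all((depths >= lo) & (depths <= hi), axis=1)
    if not valid.any():
        raise QualityError("no valid samples in trajectory; trial excluded")

    t = traj.timestamps
    lm = traj.landmarks.copy()
    good = np.flatnonzero(valid)
    bad = np.flatnonzero(~valid)
    if bad.size:
        flat = lm.reshape(n, -1)
        for col in range(flat.shape[1]):
            # np.interp holds the edge values for out-of-range queries,
            # which implements the nearest-valid-hold edge rule
            flat[bad, col] = np.interp(t[bad], t[good], flat[good, col])
        lm = flat.reshape(n, N_LANDMARKS, 3)

    return HandTrajectory(
        timestamps=t,
        landmarks=lm,
        valid=valid,
        interpolated=~valid,
        hand_label=traj.hand_label,
    )


@dataclass
class ReconstructionReport:
    """Quality summary of one bundle reconstruction."""

    n_rgb_frames: int
    n_depth_frames: int
    interpolated_frac: float
    in_view_frac: float


def reconstruct_bundle(
    bundle_dir: str | Path,
    detector: LandmarkDetector,
    config: PipelineConfig | None = None,
    hand_label: str = "right",
) -> tuple[HandTrajectory, ReconstructionReport]:
    """Reconstruct a hand trajectory from a capture bundle on disk.

    Expects ``depth.tar`` and ``calibration/`` under ``bundle_dir``. The
    detector runs per RGB frame; bundles rendered without RGB rasters
    (oracle-track workflows) pass blank frames to the adapter.

    The composite is built over all returning depth pixels and the
    15-45 cm validity window is applied per landmark to the depth of the
    selected composite entry, so a landmark over an out-of-range region
    invalidates the sample instead of silently lifting to a far point.
    """
    config = config or PipelineConfig()
    bundle = Path(bundle_dir)
    rig = read_rig_calibration(bundle / "calibration")
    depth_frames = read_depth_archive(
        bundle / "depth.tar", rig.timestamps_depth
    )
    depth_by_index = {f.frame_index: f for f in depth_frames}

    pairings = pair_frames(
        rig.timestamps_rgb, rig.timestamps_depth, threshold=config.pairing_threshold_s
    )

    n = len(rig.timestamps_rgb)
    lm_world = np.zeros((n, N_LANDMARKS, 3))
    lm_depths = np.full((n, N_LANDMARKS), np.nan)
    detected = np.zeros(n, dtype=bool)
    in_view = np.zeros(n, dtype=bool)
    blank = np.zeros((rig.rgb_size[1], rig.rgb_size[0], 3), dtype=np.uint8)
    composites: dict[int, RGBDepthComposite] = {}

    for pairing in pairings:
        i = pairing.rgb_index
        frame = RGBFrame(
            timestamp=float(rig.timestamps_rgb[i]), pixels=blank, frame_index=i
        )
        lm2d = detect_landmarks_2d(frame, detector, rgb_size=rig.rgb_size)
        detected[i] = lm2d.detected
        if not lm2d.detected or pairing.missing_depth:
            continue
        j = pairing.depth_index
        if j not in composites:
            # permissive range here; the 15-45 cm rule is applied per
            # landmark below, on the selected entries
            composites[j] = build_composite(
                depth_by_index[j], rig, j, i, valid_range=(1e-3, np.inf)
            )
        composite = composites[j]
        if len(composite) == 0:
            continue
        world, depths = lift_landmarks(lm2d, composite)
        lm_world[i] = world
        lm_depths[i] = depths
        in_view[i] = True

    if not detected.any():
        raise QualityError("detector found no hand in any frame; trial excluded")

    lo, hi = config.depth_valid_m
    with np.errstate(invalid="ignore"):
        depth_ok = np.all((lm_depths >= lo) & (lm_depths <= hi), axis=1)
    valid0 = detected & in_view & depth_ok

    raw = HandTrajectory(
        timestamps=rig.timestamps_rgb,
        landmarks=lm_world,
        valid=valid0,
        hand_label=hand_label,
    )
    traj = validate_and_interpolate(
        raw, pairings=pairings, depth_valid_m=config.depth_valid_m
    )
    report = ReconstructionReport(
        n_rgb_frames=n,
        n_depth_frames=len(depth_frames),
        interpolated_frac=float(traj.interpolated.mean()),
        in_view_frac=float((in_view & depth_ok & detected).mean()),
    )
    return traj, report
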