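"""Synthetic tapping trajectories and a virtual RGB-depth camera rig.

Ground-truthed fixtures for every pipeline stage, with no device data:

* :func:`simulate_tapping_trajectory` builds a 21-landmark hand whose
  thumb-index separation is a concatenation of raised-cosine open-close
  cycles (zero velocity at each closure, so consecutive cycles join
  smoothly even when amplitudes differ). Per-cycle amplitude carries
  multiplicative dispersion and an optional geometric decrement (the
  sequence effect); per-cycle duration carries its own dispersion
  (dysrhythmia); the apex position within a cycle can be skewed to
  decouple opening from closing velocity. The exact per-cycle table used
  is returned alongside the trajectory.
* :func:`render_virtual_capture` renders a trajectory through a rigid
  virtual rig (640x360 @ 30 Hz RGB, 512x512 @ 45 Hz depth by default)
  into a readable capture bundle: PGM depth archive with integer
  millimeter ray lengths splatted as small discs around each projected
  landmark, calibration text files, and an oracle 2D landmark track (the
  exact RGB projection of ground truth) standing in for a neural
  detector.
* :func:`make_cohort` draws participant-level tapping profiles around
  group-level means (healthy-control-like vs Parkinson-like) and runs
  the kinematics pipeline per trial, returning trial records plus the
  generating truth for recovery tests.

Closed forms used by the oracles: a raised-cosine cycle of amplitude
``A``, duration ``D`` and apex fraction ``c`` has peak opening velocity
``pi*A/(2*c*D)`` and peak closing velocity ``pi*A/(2*(1-c)*D)``; its
path length is ``2*A``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ContractError, GenerationError
from .formats import (
    DEPTH_SHAPE,
    N_LANDMARKS,
    RGB_SIZE,
    CameraRig,
    LookUpTable,
    write_depth_archive,
    write_rgb_archive,
    write_rig_calibration,
)
from .geometry import apply_transform, invert_rigid
from .kinematics import TrialMetrics, trial_metrics_from_trajectory
from .reconstruct import INDEX_TIP, THUMB_TIP, HandTrajectory


@dataclass
class TapProfile:
    """Generating parameters of one synthetic tapping trial.

    ``base_amplitude`` (cm) and ``base_frequency`` (Hz) set the mean tap;
    ``amp_cv``/``freq_cv`` the cycle-to-cycle dispersion; ``vel_cv``
    jitters the within-cycle apex position, decoupling opening from
    closing velocity; ``decrement_rate`` is the fractional amplitude loss
    per cycle (sequence effect). Defaults are a healthy-control-like tap.
    """

    base_amplitude: float = 11.3  # cm
    base_frequency: float = 3.38  # Hz
    amp_cv: float = 0.24
    freq_cv: float = 0.12
    vel_cv: float = 0.0
    decrement_rate: float = 0.0
    close_distance: float = 1.0  # cm, thumb-index separation at closure
    trial_duration: float = 20.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_amplitude <= 0 or self.base_frequency <= 0:
            raise ContractError("base amplitude and frequency must be positive")
        if min(self.amp_cv, self.freq_cv, self.vel_cv) < 0:
            raise ContractError("dispersion parameters must be non-negative")
        if not 0 <= self.decrement_rate < 1:
            raise ContractError("decrement_rate must be in [0, 1)")

    @classmethod
    def healthy_control(cls, seed: int = 0, **overrides) -> "TapProfile":
        """Healthy-control-like profile (large, fast, regular taps)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def parkinsonian(cls, seed: int = 0, **overrides) -> "TapProfile":
        """Parkinson-like profile: smaller amplitude, more cycle-to-cycle
        variability, and a mild amplitude decrement."""
        defaults = dict(
            base_amplitude=8.40,
            base_frequency=3.42,
            amp_cv=0.34,
            freq_cv=0.16,
            decrement_rate=0.004,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


def _default_depth_pose() -> np.ndarray:
    """Depth-camera pose in world: a small off-axis rotation + offset so
    the transform chain is exercised while the hand stays in view."""
    ang = np.deg2rad(2.0)
    c, s = np.cos(ang), np.sin(ang)
    T = np.eye(4)
    T[:3, :3] = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    T[:3, 3] = [0.015, -0.010, 0.005]
    return T


def _default_rig2cam() -> np.ndarray:
    ang = np.deg2rad(-3.0)
    c, s = np.cos(ang), np.sin(ang)
    T = np.eye(4)
    T[:3, :3] = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    T[:3, 3] = [0.008, 0.004, -0.006]
    return T


def _default_rgb_pose() -> np.ndarray:
    T = _default_depth_pose()
    T = T.copy()
    T[:3, 3] += T[:3, :3] @ np.array([0.032, 0.0, 0.0])  # ~3 cm baseline
    return T


@dataclass
class VirtualRigSpec:
    """Geometry and sampling of the virtual head-worn camera rig."""

    K_rgb: np.ndarray = field(
        default_factory=lambda: np.array(
            [[450.0, 0.0, 319.5], [0.0, 450.0, 179.5], [0.0, 0.0, 1.0]]
        )
    )
    rgb_size: tuple[int, int] = RGB_SIZE  # (width, height)
    depth_size: tuple[int, int] = DEPTH_SHAPE  # (rows, cols)
    rgb_rate: float = 30.0  # Hz
    depth_rate: float = 45.0  # Hz
    depth_focal: float = 256.0  # px, pinhole used to build the ray LUT
    depth_pose: np.ndarray = field(default_factory=_default_depth_pose)
    rgb_pose: np.ndarray = field(default_factory=_default_rgb_pose)
    rig2cam_depth: np.ndarray = field(default_factory=_default_rig2cam)
    depth_noise_sd_mm: float = 0.0
    drop_fraction: float = 0.0
    splat_radius_px: int = 3
    #: start offset of the depth clock relative to the RGB clock;
    #: None -> a third of the depth period (interleaved, realistic)
    depth_clock_offset_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rgb_rate <= 0 or self.depth_rate <= 0:
            raise ContractError("frame rates must be positive")
        if not 0 <= self.drop_fraction < 1:
            raise ContractError("drop_fraction must be in [0, 1)")

    def make_lut(self) -> LookUpTable:
        """Pinhole ray LUT: unit ray directions per depth pixel."""
        h, w = self.depth_size
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        v, u = np.mgrid[0:h, 0:w]
        rays = np.stack(
            [(u - cx) / self.depth_focal, (v - cy) / self.depth_focal, np.ones((h, w))],
            axis=2,
        )
        return LookUpTable(rays=rays)

    def depth_pixel(self, p_cam: np.ndarray) -> np.ndarray:
        """Continuous (u, v) depth pixel of depth-camera-frame points."""
        h, w = self.depth_size
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        u = self.depth_focal * p_cam[..., 0] / p_cam[..., 2] + cx
        v = self.depth_focal * p_cam[..., 1] / p_cam[..., 2] + cy
        return np.stack([u, v], axis=-1)


#: Static landmark offsets (meters) of the 20 non-thumb landmarks relative
#: to the hand center, a schematic open-palm layout of the standard
#: 21-point topology; the thumb tip (index 4) moves along the tap axis.
def _hand_layout() -> np.ndarray:
    rng = np.random.default_rng(20240101)
    offsets = np.zeros((N_LANDMARKS, 3))
    # wrist + palm base
    offsets[0] = [-0.01, 0.05, 0.01]
    # four fingers: MCP/PIP/DIP/TIP chains (indices 5..20), index finger up
    for f, base_x in enumerate([-0.015, -0.005, 0.005, 0.015]):
        for j in range(4):
            offsets[5 + 4 * f + j] = [base_x, 0.03 - 0.015 * (j + 1), 0.0]
    # thumb chain (1..4); tip overwritten by the tap waveform
    for j in range(4):
        offsets[1 + j] = [-0.02 - 0.008 * j, 0.035 - 0.012 * j, 0.005]
    offsets += rng.normal(0.0, 0.0005, offsets.shape)  # break exact symmetry
    return offsets


_HAND_OFFSETS = _hand_layout()

#: Default hand-center position (meters, world frame): ~34 cm in front of
#: the depth camera, placed so the full anatomical tap range stays inside
#: both camera frusta and the 15-45 cm depth validity window.
HAND_CENTER = np.array([0.06, 0.0, 0.34])

#: Unit direction along which the thumb tip opens away from the index tip.
_TAP_AXIS = np.array([0.70, 0.20, 0.69])
_TAP_AXIS = _TAP_AXIS / np.linalg.norm(_TAP_AXIS)

#: Anatomical ceiling on thumb-index separation (cm); per-cycle amplitude
#: draws are capped so closure distance + amplitude never exceeds it.
MAX_SPAN_CM = 16.0


def simulate_tapping_trajectory(
    profile: TapProfile,
    rate: float = 60.0,
    hand_center: np.ndarray = HAND_CENTER,
    hand_label: str = "right",
) -> tuple[HandTrajectory, pd.DataFrame]:
    """Generate a ground-truth tapping hand trajectory.

    Returns the trajectory (world meters, sampled at ``rate``) and the
    exact per-cycle table: ``t_start, t_end, Amp, Dur, Freq, MaxOpenVel,
    MaxCloseVel, apex_frac`` in trial-clock seconds / cm / Hz / cm/s.
    """
    rng = np.random.default_rng(profile.seed)
    T = profile.trial_duration

    # draw cycles until the trial is covered
    rows = []
    t = 0.0
    k = 0
    while t < T:
        amp = (
            profile.base_amplitude
            * (1.0 - profile.decrement_rate) ** k
            * max(0.05, 1.0 + profile.amp_cv * rng.standard_normal())
        )
        amp = min(amp, MAX_SPAN_CM - profile.close_distance)
        dur = (1.0 / profile.base_frequency) * max(
            0.2, 1.0 + profile.freq_cv * rng.standard_normal()
        )
        apex = float(np.clip(0.5 * (1.0 + profile.vel_cv * rng.standard_normal()),
                             0.2, 0.8))
        rows.append(
            dict(
                cycle=k,
                t_start=t,
                t_end=t + dur,
                Amp=amp,
                Dur=dur,
                Freq=1.0 / dur,
                MaxOpenVel=np.pi * amp / (2.0 * apex * dur),
                MaxCloseVel=np.pi * amp / (2.0 * (1.0 - apex) * dur),
                apex_frac=apex,
            )
        )
        t += dur
        k += 1
    truth = pd.DataFrame(rows)

    n = int(np.floor(T * rate)) + 1
    ts = np.arange(n) / rate
    dist_cm = np.full(n, profile.close_distance)
    for row in rows:
        sel = (ts >= row["t_start"]) & (ts < row["t_end"])
        tau = (ts[sel] - row["t_start"]) / row["Dur"]
        c = row["apex_frac"]
        # phase runs 0..1 over the cycle, 1/2 at the apex
        phase = np.where(tau < c, tau / (2.0 * c), 0.5 + (tau - c) / (2.0 * (1.0 - c)))
        dist_cm[sel] += row["Amp"] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))

    landmarks = np.tile(hand_center + _HAND_OFFSETS, (n, 1, 1))
    index_tip = landmarks[:, INDEX_TIP]
    landmarks[:, THUMB_TIP] = index_tip - _TAP_AXIS * (dist_cm[:, None] * 1e-2)

    traj = HandTrajectory(
        timestamps=ts,
        landmarks=landmarks,
        valid=np.ones(n, dtype=bool),
        hand_label=hand_label,
    )
    return traj, truth


def cycles_in_window(truth: pd.DataFrame, t0: float, t1: float) -> pd.DataFrame:
    """Ground-truth cycles recoverable from the window [t0, t1].

    Both bounding closures must lie strictly inside the window, since a
    minimum sitting exactly on a window edge is not detectable."""
    return truth.loc[(truth["t_start"] > t0) & (truth["t_end"] < t1)]


class OracleDetector:
    """Detector adapter replaying a precomputed normalized landmark track.

    Frames are consumed in capture order (one call per RGB frame); call
    :meth:`reset` before re-running a bundle.
    """

    def __init__(self, coords_norm: np.ndarray, detected: np.ndarray):
        self.coords_norm = np.asarray(coords_norm, dtype=float)
        self.detected = np.asarray(detected, dtype=bool)
        self._cursor = 0

    @classmethod
    def from_csv(cls, path: str | Path) -> "OracleDetector":
        df = pd.read_csv(path)
        n = len(df)
        coords = np.empty((n, N_LANDMARKS, 2))
        for i in range(N_LANDMARKS):
            coords[:, i, 0] = df[f"lm{i:02d}_u"]
            coords[:, i, 1] = df[f"lm{i:02d}_v"]
        return cls(coords, df["detected"].to_numpy(dtype=bool))

    def reset(self) -> None:
        self._cursor = 0

    def detect(self, pixels: np.ndarray) -> np.ndarray | None:
        if self._cursor >= len(self.coords_norm):
            raise ContractError("oracle track exhausted; call reset()")
        i = self._cursor
        self._cursor += 1
        return self.coords_norm[i] if self.detected[i] else None


def _splat_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dv, du = np.meshgrid(r, r, indexing="ij")
    keep = du**2 + dv**2 <= radius**2
    return np.column_stack([du[keep], dv[keep]])


def render_virtual_capture(
    traj: HandTrajectory,
    rig_spec: VirtualRigSpec,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
    min_in_view_frac: float = 0.75,
    write_rgb: bool = False,
) -> Path:
    """Render a trajectory into a readable capture bundle on disk.

    Writes ``depth.tar``, ``calibration/``, the oracle 2D landmark track
    ``oracle_landmarks.csv``, and a ``ground_truth.json`` sidecar. Depth
    frames carry integer-millimeter ray lengths splatted in discs of
    ``splat_radius_px`` around each projected landmark; optional Gaussian
    depth noise and frame drops are applied. Raises
    :class:`GenerationError` when the hand is in view (all landmarks in
    both frames, tips within 15-45 cm) for less than ``min_in_view_frac``
    of RGB samples.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rig_spec.seed)

    T = float(traj.timestamps[-1] - traj.timestamps[0])
    t0 = float(traj.timestamps[0])
    ts_rgb = t0 + np.arange(int(np.floor(T * rig_spec.rgb_rate)) + 1) / rig_spec.rgb_rate
    # default depth clock offset: a third of the depth period, so RGB-depth
    # offsets are nonzero but below the missing-frame threshold
    clock_off = rig_spec.depth_clock_offset_s
    if clock_off is None:
        clock_off = 1.0 / (3.0 * rig_spec.depth_rate)
    ts_depth = t0 + clock_off + np.arange(
        int(np.floor(T * rig_spec.depth_rate))
    ) / rig_spec.depth_rate

    def sample(ts: np.ndarray) -> np.ndarray:
        flat = traj.landmarks.reshape(len(traj.timestamps), -1)
        cols = [np.interp(ts, traj.timestamps, flat[:, j]) for j in range(flat.shape[1])]
        return np.stack(cols, axis=1).reshape(len(ts), N_LANDMARKS, 3)

    lm_rgb = sample(ts_rgb)  # (n_rgb, 21, 3) world
    lm_depth = sample(ts_depth)

    # --- oracle landmark track + in-view accounting (RGB clock)
    w, h = rig_spec.rgb_size
    inv_rgb = invert_rigid(rig_spec.rgb_pose)
    inv_depth = invert_rigid(rig_spec.depth_pose)
    coords_norm = np.zeros((len(ts_rgb), N_LANDMARKS, 2))
    detected = np.zeros(len(ts_rgb), dtype=bool)
    in_view = np.zeros(len(ts_rgb), dtype=bool)
    dh, dw = rig_spec.depth_size
    for i in range(len(ts_rgb)):
        p_cam = apply_transform(inv_rgb, lm_rgb[i])
        if np.any(p_cam[:, 2] <= 0):
            continue
        uvz = p_cam @ rig_spec.K_rgb.T
        uv = uvz[:, :2] / uvz[:, 2:3]
        ok_rgb = np.all((uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h))
        p_dcam = apply_transform(inv_depth, lm_rgb[i])
        duv = rig_spec.depth_pixel(p_dcam)
        ok_depth = np.all(
            (duv[:, 0] >= 0) & (duv[:, 0] < dw) & (duv[:, 1] >= 0) & (duv[:, 1] < dh)
        )
        ray = np.linalg.norm(p_dcam[[THUMB_TIP, INDEX_TIP]], axis=1)
        ok_range = np.all((ray >= 0.15) & (ray <= 0.45))
        if ok_rgb:
            coords_norm[i] = uv / np.array([w, h])
            detected[i] = True
        in_view[i] = bool(ok_rgb and ok_depth and ok_range)

    frac = float(in_view.mean())
    if frac < min_in_view_frac:
        raise GenerationError(
            f"hand in view for {100 * frac:.1f}% of samples "
            f"(< {100 * min_in_view_frac:.0f}%); adjust the scene"
        )

    # --- depth frames: disc splats of ray-length mm around each landmark
    offsets = _splat_offsets(rig_spec.splat_radius_px)
    keep = np.ones(len(ts_depth), dtype=bool)
    if rig_spec.drop_fraction > 0:
        n_drop = int(round(rig_spec.drop_fraction * len(ts_depth)))
        drop_idx = rng.choice(len(ts_depth), size=n_drop, replace=False)
        keep[drop_idx] = False

    frames = []
    for i in np.flatnonzero(keep):
        img = np.zeros(rig_spec.depth_size, dtype=np.uint16)
        p_dcam = apply_transform(inv_depth, lm_depth[i])
        good = p_dcam[:, 2] > 0
        duv = rig_spec.depth_pixel(p_dcam[good])
        rays_mm = np.linalg.norm(p_dcam[good], axis=1) * 1e3
        if rig_spec.depth_noise_sd_mm > 0:
            rays_mm = rays_mm + rng.normal(0.0, rig_spec.depth_noise_sd_mm, len(rays_mm))
        order = np.argsort(rays_mm)[::-1]  # far first; near splats overwrite
        for j in order:
            u0, v0 = int(round(duv[j, 0])), int(round(duv[j, 1]))
            uu = u0 + offsets[:, 0]
            vv = v0 + offsets[:, 1]
            ok = (uu >= 0) & (uu < dw) & (vv >= 0) & (vv < dh)
            img[vv[ok], uu[ok]] = np.uint16(np.clip(round(rays_mm[j]), 1, 65535))
        frames.append(img)

    write_depth_archive(out / "depth.tar", frames)
    ts_depth_kept = ts_depth[keep]

    # --- calibration files
    rig2world = rig_spec.depth_pose @ rig_spec.rig2cam_depth
    rig = CameraRig(
        K_rgb=rig_spec.K_rgb,
        cam2world_rgb=np.tile(rig_spec.rgb_pose, (len(ts_rgb), 1, 1)),
        rig2cam_depth=rig_spec.rig2cam_depth,
        rig2world_depth=np.tile(rig2world, (len(ts_depth_kept), 1, 1)),
        lut=rig_spec.make_lut(),
        rgb_size=rig_spec.rgb_size,
        timestamps_rgb=ts_rgb,
        timestamps_depth=ts_depth_kept,
    )
    write_rig_calibration(out / "calibration", rig)

    if write_rgb:
        blank = np.zeros((h, w, 3), dtype=np.uint8)
        write_rgb_archive(out / "rgb.tar", [blank] * len(ts_rgb))

    # --- oracle track + truth sidecar
    cols: dict[str, np.ndarray] = {"frame_index": np.arange(len(ts_rgb))}
    for i in range(N_LANDMARKS):
        cols[f"lm{i:02d}_u"] = coords_norm[:, i, 0]
        cols[f"lm{i:02d}_v"] = coords_norm[:, i, 1]
    cols["detected"] = detected.astype(int)
    pd.DataFrame(cols).to_csv(out / "oracle_landmarks.csv", index=False)

    sidecar = {
        "seed": rig_spec.seed,
        "in_view_frac": frac,
        "n_rgb_frames": len(ts_rgb),
        "n_depth_frames": int(keep.sum()),
        "n_depth_dropped": int((~keep).sum()),
    }
    if truth is not None:
        sidecar["cycles"] = truth.to_dict(orient="records")
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation

#: Group-level parameter distributions (mean, SD) for participant draws;
#: healthy-control and Parkinson-like values follow published cohort
#: moments for unconstrained finger tapping.
GROUP_PARAMS = {
    "HC": {
        "base_amplitude": (11.3, 4.1),
        "base_frequency": (3.38, 0.84),
        "amp_cv": (0.24, 0.09),
        "freq_cv": (0.12, 0.06),
        "decrement_rate": (0.0, 0.0),
    },
    "PD": {
        "base_amplitude": (8.40, 4.7),
        "base_frequency": (3.42, 0.87),
        "amp_cv": (0.34, 0.15),
        "freq_cv": (0.16, 0.09),
        "decrement_rate": (0.004, 0.002),
    },
}

_PARAM_CLIP = {
    "base_amplitude": (1.5, 25.0),
    "base_frequency": (1.0, 6.5),
    "amp_cv": (0.02, 0.6),
    "freq_cv": (0.02, 0.5),
    "decrement_rate": (0.0, 0.02),
}

#: Within-participant between-trial multiplicative jitter SD.
_TRIAL_JITTER = 0.05


def make_cohort(
    n_hc: int,
    n_pd: int,
    effect_spec: dict | str | None = None,
    seed: int = 0,
    trials_per_participant: int = 2,
    trial_duration: float = 20.0,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort and compute per-trial metrics.

    Participant-level tapping profiles are drawn around group-level
    means; each participant contributes ``trials_per_participant`` trials
    (alternating hands) run through the signal-level kinematics pipeline.
    ``effect_spec='null'`` draws both groups from the healthy-control
    distribution (exchangeable groups); a dict overrides individual PD
    parameter (mean, SD) pairs. Returns (records, truth): per-trial
    metric records and the per-participant generating parameters.
    """
    if n_hc < 2 or n_pd < 2:
        raise ContractError("need at least two participants per group")
    rng = np.random.default_rng(seed)
    params = {"HC": GROUP_PARAMS["HC"], "PD": dict(GROUP_PARAMS["PD"])}
    if effect_spec == "null":
        params["PD"] = GROUP_PARAMS["HC"]
    elif isinstance(effect_spec, dict):
        params["PD"].update(effect_spec)

    records = []
    truth_rows = []
    pid = 0
    for group, n in (("HC", n_hc), ("PD", n_pd)):
        for _ in range(n):
            pid += 1
            drawn = {}
            for name, (mu, sd) in params[group].items():
                lo, hi = _PARAM_CLIP[name]
                drawn[name] = float(np.clip(mu + sd * rng.standard_normal(), lo, hi))
            truth_rows.append(dict(participant=f"P{pid:03d}", group=group, **drawn))
            for trial in range(trials_per_participant):
                jitter = {
                    "base_amplitude": drawn["base_amplitude"]
                    * max(0.2, 1.0 + _TRIAL_JITTER * rng.standard_normal()),
                    "base_frequency": drawn["base_frequency"]
                    * max(0.2, 1.0 + _TRIAL_JITTER * rng.standard_normal()),
                }
                profile = TapProfile(
                    base_amplitude=jitter["base_amplitude"],
                    base_frequency=jitter["base_frequency"],
                    amp_cv=drawn["amp_cv"],
                    freq_cv=drawn["freq_cv"],
                    decrement_rate=drawn["decrement_rate"],
                    trial_duration=trial_duration,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                hand = "right" if trial % 2 == 0 else "left"
                traj, _ = simulate_tapping_trajectory(profile, hand_label=hand)
                metrics = trial_metrics_from_trajectory(traj, config)
                records.append(
                    dict(
                        participant=f"P{pid:03d}",
                        trial=trial,
                        hand=hand,
                        group=group,
                        **metrics.as_dict(),
                    )
                )
    return pd.DataFrame(records), pd.DataFrame(truth_rows)


def metrics_long(records: pd.DataFrame, system: str | None = None) -> pd.DataFrame:
    """Melt wide per-trial metric records into the long format consumed
    by the statistics module (participant, trial, hand, group, [system],
    metric, value)."""
    id_vars = [c for c in ("participant", "trial", "hand", "group", "system")
               if c in records.columns]
    long = records.melt(
        id_vars=id_vars, value_vars=list(TrialMetrics.FIELDS),
        var_name="metric", value_name="value",
    )
    if system is not None:
        long["system"] = system
    return long
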