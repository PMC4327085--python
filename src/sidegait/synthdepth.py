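"""Synthetic depth scenes and Get-Up-and-Go sequences with exact ground truth.

Replaces the depth sensor for tests and demos.  The scene is a wall, a
floor, and an armless chair viewed through the pinhole model; the subject
is a 2.5-D articulated figure built from capsules (thick segments with
rounded ends), each rendered at a single depth.  In side view the limbs
nearer the sensor sit 80-150 mm closer than the far ones, which is what
the tracker's depth-gap rule keys on.  Every rendered frame comes with the
exact projected pixel coordinates of the joints.

World coordinates: ``X`` lateral (mm, +X maps to larger columns), ``H``
height above the floor, ``Z`` depth from the sensor.  The subject walks
toward -X, so the body-rear direction is +X (``rear_sign = +1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .depth_core import (DEFAULT_INTRINSICS, FrameSequence, IntrinsicModel,
                         PixelCoord, round_half_up)
from .errors import RenderError
from .sideview import Trajectory

#: Walking direction sign along X (the figure faces -X).
FORWARD = -1.0


class AnthroRow(NamedTuple):
    """One printed row of the anthropometric survey table (cm units)."""

    stature: float
    head_height: float
    ratio: float          # printed stature/head ratio
    buttock_height: float
    head_to_hip: float    # printed stature - buttock height
    coefficient: float    # printed empirical hip coefficient


#: Printed survey rows, keyed by dataset number.
ANTHRO_TABLE: dict[str, AnthroRow] = {
    "10": AnthroRow(161.3, 22.56, 7.15, 84.14, 77.16, 3.42),
    "8": AnthroRow(162.77, 22.08, 7.37, 82.08, 80.61, 3.65),
    "7": AnthroRow(162.1, 21.91, 7.4, 82.21, 79.89, 3.65),
    "9": AnthroRow(161.92, 21.76, 7.44, 82.09, 79.83, 3.67),
    "51": AnthroRow(170.62, 22.31, 7.64, 86.56, 84.06, 3.77),
    "21": AnthroRow(174.72, 22.45, 7.78, 89.95, 84.77, 3.78),
    "20": AnthroRow(177.1, 22.4, 7.9, 91.16, 85.94, 3.84),
}


@dataclass
class SceneConfig:
    """Static scene geometry, camera model and sensor noise."""

    wall_depth: float = 3300.0      # mm from sensor
    sensor_height: float = 920.0    # mm above the floor
    chair_depth: float = 3000.0     # mm; 300 mm in front of the wall
    chair_x: float = 600.0          # lateral chair position, mm
    frame_height: int = 240
    frame_width: int = 320
    intrinsics: IntrinsicModel = field(default_factory=lambda: DEFAULT_INTRINSICS)
    noise_sigma: float = 0.0        # additive Gaussian depth noise, mm
    dropout_rate: float = 0.0       # fraction of pixels zeroed per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.wall_depth > self.chair_depth > 0:
            raise ValueError("need wall_depth > chair_depth > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass
class FigureConfig:
    """Articulated figure: stature plus survey-table proportions (mm)."""

    stature: float = 1700.0
    dataset: str = "51"              # ANTHRO_TABLE row supplying the ratios
    subject_depth: float = 2750.0    # torso depth during the test, mm
    limb_depth_offset: float = 110.0  # near/far limb depth split, mm
    ankle_height: float = 60.0
    front_arm_angle_deg: float = 18.0  # arm splay in the calibration pose
    front_leg_separation: float = 35.0  # half-distance between hips, mm
    hand_length: float = field(init=False)

    # capsule radii, mm (defaults for a 1.70-m figure, scaled with stature)
    head_radius: float = field(init=False)
    torso_radius_side: float = 125.0
    torso_radius_front: float = 140.0
    shoulder_bar_radius: float = 50.0
    shoulder_half_width: float = 130.0
    thigh_radius: float = 55.0
    shank_radius: float = 45.0
    arm_radius: float = 28.0
    neck_radius: float = 45.0
    foot_radius: float = 35.0
    foot_length: float = 140.0

    # derived segment lengths, mm
    head_height: float = field(init=False)
    hip_height: float = field(init=False)
    shoulder_height: float = field(init=False)
    knee_height: float = field(init=False)
    thigh_length: float = field(init=False)
    shank_length: float = field(init=False)
    trunk_length: float = field(init=False)
    upper_arm_length: float = field(init=False)
    forearm_length: float = field(init=False)

    def __post_init__(self) -> None:
        row = ANTHRO_TABLE[self.dataset]
        s = self.stature
        scale = s / 1700.0
        # shoulder_bar_radius stays at 40 mm: the widening row must sit
        # one 40-mm shift above the shoulder joint at every stature
        for name in ("torso_radius_side", "torso_radius_front",
                     "shoulder_half_width", "thigh_radius", "shank_radius",
                     "arm_radius", "neck_radius", "foot_radius",
                     "foot_length"):
            setattr(self, name, getattr(self, name) * scale)
        self.hand_length = 0.065 * s
        self.head_height = s * row.head_height / row.stature
        self.hip_height = s * row.buttock_height / row.stature
        # shoulder joint sits 40 mm below the shoulder surface, which is
        # one neck height (100 mm) below the top of the head
        self.shoulder_height = s - self.head_height - 140.0
        self.shank_length = 0.2 * s
        self.knee_height = self.ankle_height + self.shank_length
        self.thigh_length = self.hip_height - self.knee_height
        self.trunk_length = self.shoulder_height - self.hip_height
        self.head_radius = self.head_height / 2.0
        # the straight arm plus the hand must reach just past the hip row
        # in the calibration pose so the arm-body gap test can succeed
        reach = (self.trunk_length + 70.0) / math.cos(
            math.radians(self.front_arm_angle_deg))
        self.upper_arm_length = (reach - self.hand_length) / 2.0
        self.forearm_length = self.upper_arm_length
        if min(self.thigh_length, self.trunk_length,
               self.upper_arm_length) <= 0:
            raise ValueError("degenerate figure proportions")


@dataclass
class PoseFrame:
    """Sagittal-plane pose for one frame (angles in degrees from vertical).

    Positive leg/arm angles swing the limb toward the walking direction;
    ``trunk_lean`` tilts the trunk forward.
    """

    pelvis_x: float
    pelvis_h: float
    trunk_lean: float = 0.0
    thigh_near: float = 0.0
    thigh_far: float = 0.0
    shank_near: float = 0.0
    shank_far: float = 0.0
    arm_near: float = 0.0
    arm_far: float = 0.0
    forearm_near: float = 0.0
    forearm_far: float = 0.0
    phase: str = "standing"


# ---------------------------------------------------------------------------
# projection and rasterization
# ---------------------------------------------------------------------------

def _project(cfg: SceneConfig, x: float, h: float, z: float,
             ) -> tuple[float, float]:
    """World (X, H, Z) -> float (row, col)."""
    intr = cfg.intrinsics
    col = intr.center_x + intr.focal_x * x / z
    row = intr.center_y + intr.focal_y * (cfg.sensor_height - h) / z
    return row, col


def _draw_capsule(depth: np.ndarray, cfg: SceneConfig,
                  p1: tuple[float, float], p2: tuple[float, float],
                  radius_mm: float, z: float) -> None:
    """Rasterize a capsule between two (X, H) points at depth ``z`` (z-min)."""
    r1, c1 = _project(cfg, p1[0], p1[1], z)
    r2, c2 = _project(cfg, p2[0], p2[1], z)
    rad = cfg.intrinsics.focal_x * radius_mm / z
    r_lo = max(0, int(math.floor(min(r1, r2) - rad - 1)))
    r_hi = min(depth.shape[0], int(math.ceil(max(r1, r2) + rad + 2)))
    c_lo = max(0, int(math.floor(min(c1, c2) - rad - 1)))
    c_hi = min(depth.shape[1], int(math.ceil(max(c1, c2) + rad + 2)))
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    vr, vc = r2 - r1, c2 - c1
    norm2 = vr * vr + vc * vc
    if norm2 == 0:
        dist = np.hypot(rr - r1, cc - c1)
    else:
        t = np.clip(((rr - r1) * vr + (cc - c1) * vc) / norm2, 0.0, 1.0)
        dist = np.hypot(rr - (r1 + t * vr), cc - (c1 + t * vc))
    hit = dist <= rad
    patch = depth[r_lo:r_hi, c_lo:c_hi]
    patch[hit] = np.minimum(patch[hit], z)


def scene_depth(cfg: SceneConfig) -> np.ndarray:
    """Clean (noise-free) depth map of the empty scene, integer mm."""
    rows = np.arange(cfg.frame_height, dtype=float)[:, None]
    cols = np.arange(cfg.frame_width, dtype=float)[None, :]
    intr = cfg.intrinsics
    depth = np.full((cfg.frame_height, cfg.frame_width), cfg.wall_depth)
    t = (rows - intr.center_y) / intr.focal_y  # downward ray slope
    with np.errstate(divide="ignore"):
        z_floor = np.where(t > 0, cfg.sensor_height / np.where(t > 0, t, 1.0),
                           np.inf)
    depth = np.minimum(depth, np.broadcast_to(z_floor, depth.shape))

    # chair seat: horizontal surface at seat height, limited Z range
    seat_h, seat_z0 = 450.0, cfg.chair_depth
    seat_z1 = min(cfg.chair_depth + 300.0, cfg.wall_depth)
    with np.errstate(divide="ignore"):
        z_seat = np.where(t > 0, (cfg.sensor_height - seat_h)
                          / np.where(t > 0, t, 1.0), np.inf)
    x_at_seat = (cols - intr.center_x) * z_seat / intr.focal_x
    seat_hit = ((z_seat >= seat_z0) & (z_seat <= seat_z1)
                & (np.abs(x_at_seat - cfg.chair_x) <= 225.0))
    depth = np.where(seat_hit & (z_seat < depth), z_seat, depth)

    # chair backrest: vertical plane near the wall side of the seat
    back_z = seat_z1
    h_at_back = cfg.sensor_height - t * back_z
    x_at_back = (cols - intr.center_x) * back_z / intr.focal_x
    back_hit = ((h_at_back >= seat_h) & (h_at_back <= 950.0)
                & (np.abs(x_at_back - cfg.chair_x) <= 225.0))
    depth = np.where(back_hit & (back_z < depth), back_z, depth)
    return np.floor(depth + 0.5).astype(np.int32)


def _apply_noise(frame: np.ndarray, cfg: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = frame.astype(float)
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=out.shape)
    out = np.maximum(0.0, np.floor(out + 0.5))
    if cfg.dropout_rate > 0:
        out[rng.random(out.shape) < cfg.dropout_rate] = 0.0
    return out.astype(np.int32)


def render_background(cfg: SceneConfig, n_frames: int = 100,
                      rng: np.random.Generator | None = None) -> FrameSequence:
    """Empty-scene frames with per-frame noise (deterministic per seed)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    clean = scene_depth(cfg)
    return FrameSequence([_apply_noise(clean, cfg, rng)
                          for _ in range(n_frames)])


# ---------------------------------------------------------------------------
# figure kinematics
# ---------------------------------------------------------------------------

def _dir_down(angle_deg: float) -> tuple[float, float]:
    """(dX, dH) unit vector ``angle_deg`` forward of straight down."""
    a = math.radians(angle_deg)
    return (FORWARD * math.sin(a), -math.cos(a))


def side_joint_positions(fig: FigureConfig, pose: PoseFrame,
                         ) -> dict[str, tuple[float, float]]:
    """Forward kinematics: joint (X, H) positions for a side-view pose."""
    lean = math.radians(pose.trunk_lean)
    trunk_dir = (FORWARD * math.sin(lean), math.cos(lean))
    hip = (pose.pelvis_x, pose.pelvis_h)
    shoulder = (hip[0] + fig.trunk_length * trunk_dir[0],
                hip[1] + fig.trunk_length * trunk_dir[1])
    head_off = 140.0 + fig.head_height / 2.0
    head = (shoulder[0] + head_off * trunk_dir[0],
            shoulder[1] + head_off * trunk_dir[1])
    joints = {"hip": hip, "shoulder": shoulder, "head": head}
    for side, thigh_a, shank_a, arm_a, fore_a in (
            ("near", pose.thigh_near, pose.shank_near, pose.arm_near,
             pose.forearm_near),
            ("far", pose.thigh_far, pose.shank_far, pose.arm_far,
             pose.forearm_far)):
        d = _dir_down(thigh_a)
        knee = (hip[0] + fig.thigh_length * d[0],
                hip[1] + fig.thigh_length * d[1])
        d = _dir_down(shank_a)
        ankle = (knee[0] + fig.shank_length * d[0],
                 knee[1] + fig.shank_length * d[1])
        d = _dir_down(arm_a)
        elbow = (shoulder[0] + fig.upper_arm_length * d[0],
                 shoulder[1] + fig.upper_arm_length * d[1])
        d = _dir_down(fore_a)
        wrist = (elbow[0] + fig.forearm_length * d[0],
                 elbow[1] + fig.forearm_length * d[1])
        joints.update({f"knee_{side}": knee, f"ankle_{side}": ankle,
                       f"elbow_{side}": elbow, f"wrist_{side}": wrist})
    return joints


def render_person(cfg: SceneConfig, fig: FigureConfig, pose: PoseFrame,
                  view: str = "side",
                  background: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, dict[str, PixelCoord]]:
    """Composite the figure over the clean scene; return exact joint pixels.

    Side view returns ground truth for the six tracked joints (near side);
    front view additionally returns the wrist of the frame-left arm.
    """
    depth = (scene_depth(cfg) if background is None
             else background.copy()).astype(float)
    if view == "front":
        frame, gt = _render_front(depth, cfg, fig)
    elif view == "side":
        frame, gt = _render_side(depth, cfg, fig, pose)
    else:
        raise ValueError(f"unknown view {view!r}")
    h, w = depth.shape
    for name, pt in gt.items():
        if not (0 <= pt.row < h and 0 <= pt.col < w):
            raise RenderError(f"joint {name} projects outside the frame")
    return frame, gt


def _gt(cfg: SceneConfig, x: float, h: float, z: float) -> PixelCoord:
    row, col = _project(cfg, x, h, z)
    return PixelCoord(round_half_up(row), round_half_up(col))


def _render_side(depth: np.ndarray, cfg: SceneConfig, fig: FigureConfig,
                 pose: PoseFrame) -> tuple[np.ndarray, dict[str, PixelCoord]]:
    j = side_joint_positions(fig, pose)
    z_body = fig.subject_depth
    z_near = z_body - fig.limb_depth_offset
    z_far = z_body + fig.limb_depth_offset

    _draw_capsule(depth, cfg, j["hip"], j["shoulder"],
                  fig.torso_radius_side, z_body)
    _draw_capsule(depth, cfg, j["shoulder"], j["head"], fig.neck_radius,
                  z_body)
    _draw_capsule(depth, cfg, j["head"], j["head"], fig.head_radius, z_body)
    for side, z in (("far", z_far), ("near", z_near)):
        knee, ankle = j[f"knee_{side}"], j[f"ankle_{side}"]
        elbow, wrist = j[f"elbow_{side}"], j[f"wrist_{side}"]
        _draw_capsule(depth, cfg, j["hip"], knee, fig.thigh_radius, z)
        _draw_capsule(depth, cfg, knee, ankle, fig.shank_radius, z)
        toe = (ankle[0] + FORWARD * fig.foot_length, fig.foot_radius)
        _draw_capsule(depth, cfg, ankle, toe, fig.foot_radius, z)
        _draw_capsule(depth, cfg, j["shoulder"], elbow, fig.arm_radius, z)
        _draw_capsule(depth, cfg, elbow, wrist, fig.arm_radius * 0.95, z)

    gt = {"head": _gt(cfg, *j["head"], z_body),
          "shoulder": _gt(cfg, *j["shoulder"], z_body),
          "elbow": _gt(cfg, *j["elbow_near"], z_near),
          "hip": _gt(cfg, *j["hip"], z_body),
          "knee": _gt(cfg, *j["knee_near"], z_near),
          "ankle": _gt(cfg, *j["ankle_near"], z_near)}
    return np.floor(depth + 0.5).astype(np.int32), gt


def _render_front(depth: np.ndarray, cfg: SceneConfig, fig: FigureConfig,
                  ) -> tuple[np.ndarray, dict[str, PixelCoord]]:
    """Calibration pose: facing the sensor, arms splayed, legs together."""
    z = fig.subject_depth
    s = fig.stature
    sh_h, hip_h = fig.shoulder_height, fig.hip_height
    half_sh = fig.shoulder_half_width
    # torso, shoulder bar, neck, head
    _draw_capsule(depth, cfg, (0.0, hip_h), (0.0, sh_h - 100.0),
                  fig.torso_radius_front, z)
    _draw_capsule(depth, cfg, (-half_sh, sh_h), (half_sh, sh_h),
                  fig.shoulder_bar_radius, z)
    _draw_capsule(depth, cfg, (0.0, sh_h + fig.shoulder_bar_radius),
                  (0.0, s - fig.head_height), fig.neck_radius, z)
    head_c = (0.0, s - fig.head_height / 2.0)
    _draw_capsule(depth, cfg, head_c, head_c, fig.head_radius, z)

    arm = math.radians(fig.front_arm_angle_deg)
    gt: dict[str, PixelCoord] = {"head": _gt(cfg, *head_c, z)}
    for sign in (-1.0, 1.0):  # -1 = frame-left
        shoulder = (sign * half_sh, sh_h)
        d = (sign * math.sin(arm), -math.cos(arm))
        elbow = (shoulder[0] + fig.upper_arm_length * d[0],
                 shoulder[1] + fig.upper_arm_length * d[1])
        wrist = (elbow[0] + fig.forearm_length * d[0],
                 elbow[1] + fig.forearm_length * d[1])
        tip = (wrist[0] + fig.hand_length * d[0],
               wrist[1] + fig.hand_length * d[1])
        _draw_capsule(depth, cfg, shoulder, elbow, fig.arm_radius, z)
        _draw_capsule(depth, cfg, elbow, wrist, fig.arm_radius * 0.95, z)
        _draw_capsule(depth, cfg, wrist, tip, fig.arm_radius * 0.85, z)
        if sign < 0:
            gt.update({"shoulder": _gt(cfg, *shoulder, z),
                       "elbow": _gt(cfg, *elbow, z),
                       "wrist": _gt(cfg, *wrist, z)})
    gt["hip"] = _gt(cfg, 0.0, hip_h, z)
    for sign in (-1.0, 1.0):
        x = sign * fig.front_leg_separation
        hip = (x, hip_h)
        knee = (x, fig.knee_height)
        ankle = (x, fig.ankle_height)
        _draw_capsule(depth, cfg, hip, knee, fig.thigh_radius, z)
        _draw_capsule(depth, cfg, knee, ankle, fig.shank_radius, z)
        _draw_capsule(depth, cfg, ankle, (x, 40.0), fig.foot_radius, z)
        if sign < 0:
            gt.update({"knee": _gt(cfg, *knee, z),
                       "ankle": _gt(cfg, *ankle, z)})
    return np.floor(depth + 0.5).astype(np.int32), gt


def render_front_pose(cfg: SceneConfig, fig: FigureConfig,
                      ) -> tuple[np.ndarray, dict[str, PixelCoord]]:
    """Noise-free calibration frame plus ground-truth joints."""
    pose = PoseFrame(pelvis_x=0.0, pelvis_h=fig.hip_height, phase="front")
    return render_person(cfg, fig, pose, view="front")


# ---------------------------------------------------------------------------
# GUGT pose schedule
# ---------------------------------------------------------------------------

def _smoothstep(u: float) -> float:
    u = min(1.0, max(0.0, u))
    return u * u * (3.0 - 2.0 * u)


def gugt_pose_spec(fig: FigureConfig, n_frames: int,
                   seat_height: float = 450.0,
                   walk_distance: float = 1350.0,
                   n_steps: float = 2.5,
                   thigh_amplitude: float = 22.0,
                   arm_amplitude: float = 12.0) -> list[PoseFrame]:
    """Seated -> rising -> walking schedule with continuous angles."""
    if n_frames < 2:
        raise ValueError("need at least two frames")
    seat_end, rise_end = 0.18, 0.40
    pelvis_sit_h = seat_height + fig.thigh_radius * 0.5
    chair_front_x = 450.0
    poses = []
    for k in range(n_frames):
        s = k / (n_frames - 1)
        if s <= seat_end:  # seated, slight forward lean building up
            u = s / seat_end
            poses.append(PoseFrame(
                pelvis_x=chair_front_x, pelvis_h=pelvis_sit_h,
                trunk_lean=5.0 + 5.0 * u,
                thigh_near=90.0, thigh_far=90.0,
                shank_near=0.0, shank_far=0.0,
                arm_near=5.0, arm_far=5.0,
                forearm_near=5.0, forearm_far=5.0, phase="seated"))
        elif s <= rise_end:  # standing up
            u = _smoothstep((s - seat_end) / (rise_end - seat_end))
            lean = 10.0 + 18.0 * math.sin(math.pi * u)  # forward peak mid-rise
            poses.append(PoseFrame(
                pelvis_x=chair_front_x - 60.0 * u,
                pelvis_h=pelvis_sit_h + (fig.hip_height - pelvis_sit_h) * u,
                trunk_lean=lean * (1.0 - 0.85 * u) + 3.0 * u,
                thigh_near=90.0 * (1.0 - u), thigh_far=90.0 * (1.0 - u),
                shank_near=0.0, shank_far=0.0,
                arm_near=5.0 * (1.0 - u), arm_far=5.0 * (1.0 - u),
                forearm_near=5.0 * (1.0 - u), forearm_far=5.0 * (1.0 - u),
                phase="rising"))
        else:  # walking toward -X
            u = (s - rise_end) / (1.0 - rise_end)
            ramp = _smoothstep(u / 0.2) if u < 0.2 else 1.0
            ph = 2.0 * math.pi * n_steps * u
            thigh = ramp * thigh_amplitude * math.sin(ph)
            shank = ramp * thigh_amplitude * 0.85 * math.sin(ph - 0.6)
            arm = ramp * arm_amplitude * math.sin(ph + math.pi)
            poses.append(PoseFrame(
                pelvis_x=chair_front_x - 60.0 - walk_distance * u,
                pelvis_h=fig.hip_height - 10.0 * ramp
                * (1.0 - math.cos(2.0 * ph)) / 2.0,
                trunk_lean=3.0,
                thigh_near=thigh, thigh_far=-thigh,
                shank_near=shank, shank_far=-shank,
                arm_near=arm, arm_far=-arm,
                forearm_near=arm + 8.0 * ramp, forearm_far=-arm + 8.0 * ramp,
                phase="walking"))
    return poses


def simulate_gugt(cfg: SceneConfig, fig: FigureConfig, n_frames: int = 120,
                  seed: int | None = None,
                  ) -> tuple[FrameSequence, Trajectory]:
    """Render a full synthetic GUGT; deterministic for a given seed.

    Returns the (optionally noisy) depth frames and the exact six-joint
    ground-truth track of the near side.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    clean_scene = scene_depth(cfg)
    frames = []
    tracks: dict[str, list[tuple[float, float] | None]] = {
        j: [] for j in ("head", "shoulder", "elbow", "hip", "knee", "ankle")}
    for pose in gugt_pose_spec(fig, n_frames):
        frame, gt = render_person(cfg, fig, pose, view="side",
                                  background=clean_scene)
        frames.append(_apply_noise(frame, cfg, rng))
        for joint in tracks:
            pt = gt[joint]
            tracks[joint].append((float(pt.row), float(pt.col)))
    return FrameSequence(frames), Trajectory(joints=tracks)


def make_scene(noise_sigma: float = 0.0, dropout_rate: float = 0.0,
               seed: int = 0, **kwargs) -> SceneConfig:
    """Convenience constructor mirroring the published scene defaults."""
    return SceneConfig(noise_sigma=noise_sigma, dropout_rate=dropout_rate,
                       seed=seed, **kwargs)
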