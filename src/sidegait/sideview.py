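"""Per-frame side-view joint localization and sequence tracking.

Every frame is processed independently: background subtraction and largest
component give the silhouette, the near side of the body is isolated with
an 80-mm depth-gap rule, and the six joints (head, shoulder, elbow, hip,
knee, ankle) are located with the calibrated pixel distances.  Elbow and
hip use fixed-length rotating vectors anchored at the shoulder and knee.

Angle conventions (degrees, 2-degree steps):

* elbow: theta measured from the horizontal image axis, sweeping the lower
  half-plane below the shoulder; theta = 90 points straight down (rows+).
* hip: gamma measured from the upward vertical at the knee, opening toward
  the body-rear column direction (``rear_sign``); gamma = 90 points
  horizontally rearward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .background import (DEFAULT_FOREGROUND_THRESHOLD_MM, Silhouette,
                         foreground_mask, largest_silhouette)
from .depth_core import (DEFAULT_INTRINSICS, FrameSequence, IntrinsicModel,
                         PixelCoord, as_depth_frame, metric_to_pixels,
                         round_half_up)
from .errors import NoSubjectError, TrackingError
from .frontpose import ANKLE_OFFSET_MM, BodyModel

JOINT_NAMES = ("head", "shoulder", "elbow", "hip", "knee", "ankle")

#: Depth gap isolating the near side of the body (mm).
SIDE_GAP_MM = 80
#: Angular step of the rotating-vector fits (degrees).
ANGLE_STEP_DEG = 2
#: Minimum pixels an arm sub-region must hold before fitting the elbow.
MIN_ARM_PIXELS = 10


@dataclass
class NearSideRegion:
    """Silhouette pixels within the depth gap of the near body side."""

    bits: np.ndarray
    reference_depth: float

    def row_cols(self, row: int) -> np.ndarray:
        if row < 0 or row >= self.bits.shape[0]:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.bits[row])


def near_side_region(df: np.ndarray, sil: Silhouette, model: BodyModel,
                     gap_mm: float = SIDE_GAP_MM) -> NearSideRegion:
    """Isolate the body side closest to the sensor.

    Half an ankle-knee distance above the silhouette bottom, the column of
    minimal depth seeds a square window of side ``ak_dist``; window pixels
    farther than the gap from the central depth are discarded, the mean of
    the survivors is the reference depth, and the region is every valid
    silhouette pixel within the gap of that reference.
    """
    df = as_depth_frame(df)
    base_row = sil.last_row - model.ak_dist // 2
    cols = sil.row_cols(base_row)
    if cols.size:
        depths = df[base_row, cols]
        cols = cols[depths > 0]
    if cols.size == 0:
        raise TrackingError(f"no valid silhouette pixels on row {base_row}")
    center_col = int(cols[np.argmin(df[base_row, cols])])
    center_depth = int(df[base_row, center_col])

    half = model.ak_dist // 2
    r0, r1 = max(0, base_row - half), min(df.shape[0], base_row + half + 1)
    c0, c1 = max(0, center_col - half), min(df.shape[1], center_col + half + 1)
    window = df[r0:r1, c0:c1]
    in_sil = sil.bits[r0:r1, c0:c1]
    valid = in_sil & (window > 0)
    keep = valid & (np.abs(window - center_depth) <= gap_mm)
    # a central pixel that rejects most of the window is itself a noise
    # spike: fall back to the window median as the gap reference
    if keep.sum() < 0.25 * valid.sum():
        center_depth = int(np.median(window[valid]))
        keep = valid & (np.abs(window - center_depth) <= gap_mm)
    if not keep.any():
        raise TrackingError("side-selection window rejected every pixel")
    reference_depth = float(window[keep].mean())

    bits = sil.bits & (df > 0) & (np.abs(df - reference_depth) <= gap_mm)
    return NearSideRegion(bits=bits, reference_depth=reference_depth)


def locate_head_side(sil: Silhouette, model: BodyModel) -> PixelCoord:
    """Head: calibrated row shift below the silhouette top, column mean."""
    row = sil.first_row + model.shift_row
    cols = sil.row_cols(row)
    if cols.size == 0:
        raise TrackingError(f"no silhouette pixels on head row {row}")
    return PixelCoord(row, round_half_up(float(cols.mean())))


def _reproject(anchor: PixelCoord, target: PixelCoord,
               length: float) -> PixelCoord:
    """Point at ``length`` from ``anchor`` along the anchor->target ray."""
    dr, dc = target.row - anchor.row, target.col - anchor.col
    norm = math.hypot(dr, dc)
    if norm == 0:
        return anchor
    return PixelCoord(anchor.row + round_half_up(length * dr / norm),
                      anchor.col + round_half_up(length * dc / norm))


def locate_shoulder_side(sil: Silhouette, head: PixelCoord,
                         model: BodyModel) -> PixelCoord:
    """Shoulder at exactly ``hs_dist`` from the head.

    A provisional shoulder sits ``hs_dist`` rows below the head at the
    midpoint of the silhouette columns; the final joint is re-projected
    onto the head->provisional direction at the calibrated distance.
    """
    prov_row = head.row + model.hs_dist
    cols = sil.row_cols(prov_row)
    if cols.size == 0:
        raise TrackingError(f"no silhouette pixels on row {prov_row}")
    prov = PixelCoord(prov_row, round_half_up((int(cols[0]) + int(cols[-1])) / 2))
    return _reproject(head, prov, model.hs_dist)


def locate_ankle_side(region: NearSideRegion, sil: Silhouette,
                      model: BodyModel, frame_depth_mm: float,
                      intr: IntrinsicModel = DEFAULT_INTRINSICS) -> PixelCoord:
    """Ankle 40 mm above the silhouette bottom, near-side column mean."""
    row = sil.last_row - metric_to_pixels(ANKLE_OFFSET_MM, frame_depth_mm,
                                          intr, "rows")
    cols = region.row_cols(row)
    if cols.size == 0:
        raise TrackingError(f"no near-side pixels on ankle row {row}")
    return PixelCoord(row, round_half_up(float(cols.mean())))


def locate_knee_side(region: NearSideRegion, ankle: PixelCoord,
                     model: BodyModel) -> PixelCoord:
    """Knee at exactly ``ak_dist`` from the ankle (same rule as shoulder)."""
    prov_row = ankle.row - model.ak_dist
    cols = region.row_cols(prov_row)
    if cols.size == 0:
        raise TrackingError(f"no near-side pixels on knee row {prov_row}")
    prov = PixelCoord(prov_row, round_half_up((int(cols[0]) + int(cols[-1])) / 2))
    return _reproject(ankle, prov, model.ak_dist)


def raster_segment(r0: int, c0: int, r1: int, c1: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Integer raster of the segment (r0,c0)-(r1,c1).

    Steps one pixel along the major axis, rounding (half-up) the minor
    coordinate: 8-connected and endpoint-inclusive.
    """
    n = max(abs(r1 - r0), abs(c1 - c0))
    if n == 0:
        return np.array([r0]), np.array([c0])
    t = np.arange(n + 1)
    rr = np.floor(r0 + t * (r1 - r0) / n + 0.5).astype(int)
    cc = np.floor(c0 + t * (c1 - c0) / n + 0.5).astype(int)
    return rr, cc


def segment_overlap(anchor: PixelCoord, direction: tuple[float, float],
                    length: float, mask: np.ndarray) -> int:
    """Count mask pixels hit by the rasterized segment from ``anchor``.

    The segment runs from the anchor to the rounded endpoint at ``length``
    along ``direction``; out-of-frame raster pixels are ignored.
    """
    end_r = anchor.row + round_half_up(length * direction[0])
    end_c = anchor.col + round_half_up(length * direction[1])
    rr, cc = raster_segment(anchor.row, anchor.col, end_r, end_c)
    inb = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    return int(mask[rr[inb], cc[inb]].sum())


def _segment_end(anchor: PixelCoord, direction: tuple[float, float],
                 length: float) -> PixelCoord:
    return PixelCoord(anchor.row + round_half_up(length * direction[0]),
                      anchor.col + round_half_up(length * direction[1]))


def arm_subregion(df: np.ndarray, sil: Silhouette, shoulder: PixelCoord,
                  model: BodyModel, gap_mm: float = SIDE_GAP_MM) -> np.ndarray:
    """Pixels around the near arm, via the windowed depth-gap procedure.

    The square window of side ``se_dist`` is centered ``se_dist/2`` rows
    below the shoulder at the shoulder column.
    """
    df = as_depth_frame(df)
    center = PixelCoord(shoulder.row + model.se_dist // 2, shoulder.col)
    half = model.se_dist // 2
    r0 = max(0, center.row - half)
    r1 = min(df.shape[0], center.row + half + 1)
    c0 = max(0, center.col - half)
    c1 = min(df.shape[1], center.col + half + 1)
    if not (r0 <= center.row < r1 and c0 <= center.col < c1):
        raise TrackingError("arm window outside the frame")
    center_depth = int(df[center.row, center.col])
    if center_depth <= 0 or not sil.bits[center.row, center.col]:
        raise TrackingError("arm window center off the silhouette")
    window = df[r0:r1, c0:c1]
    in_sil = sil.bits[r0:r1, c0:c1]
    keep = in_sil & (window > 0) & (np.abs(window - center_depth) <= gap_mm)
    if not keep.any():
        raise TrackingError("arm window rejected every pixel")
    ref = float(window[keep].mean())
    region = np.zeros_like(sil.bits)
    region[r0:r1, c0:c1] = (in_sil & (window > 0)
                            & (np.abs(window - ref) <= gap_mm))
    return region


def locate_elbow_side(df: np.ndarray, sil: Silhouette, shoulder: PixelCoord,
                      model: BodyModel,
                      angle_step: int = ANGLE_STEP_DEG) -> PixelCoord:
    """Elbow by a rotating vector of length ``se_dist`` from the shoulder.

    theta sweeps 2..178 degrees from the horizontal through straight-down;
    the angle with maximal raster overlap with the arm sub-region wins
    (smallest angle on ties).
    """
    arm = arm_subregion(df, sil, shoulder, model)
    if arm.sum() < MIN_ARM_PIXELS:
        raise TrackingError("arm sub-region too small to fit the elbow")
    best_theta, best_count = None, 0
    for theta in range(2, 179, angle_step):
        rad = math.radians(theta)
        count = segment_overlap(shoulder, (math.sin(rad), math.cos(rad)),
                                model.se_dist, arm)
        if count > best_count:
            best_theta, best_count = theta, count
    if best_theta is None:
        raise TrackingError("no rotating-vector overlap for the elbow")
    rad = math.radians(best_theta)
    return _segment_end(shoulder, (math.sin(rad), math.cos(rad)),
                        model.se_dist)


def hip_sweep_angles(angle_step: int = ANGLE_STEP_DEG) -> list[int]:
    """gamma schedule for the hip fit: the upper half-plane at the knee.

    gamma is measured from the upward vertical, positive toward the body
    rear.  The sweep starts at 4 degrees and climbs to horizontal-rear,
    then wraps through vertical to the forward side, so a thigh tilted
    either way is reachable; ties go to the earliest angle in this order.
    """
    return (list(range(4, 91, angle_step))
            + list(range(4 - angle_step, -89, -angle_step)))


def locate_hip_side(region: NearSideRegion, knee: PixelCoord,
                    model: BodyModel, angle_step: int = ANGLE_STEP_DEG,
                    rear_sign: int = 1) -> PixelCoord:
    """Hip by a rotating vector of length ``kh_dist`` anchored at the knee.

    The segment sweeps the half-plane above the knee per
    :func:`hip_sweep_angles`; the angle with maximal overlap with the
    near-side region wins.
    """
    best_gamma, best_count = None, 0
    for gamma in hip_sweep_angles(angle_step):
        rad = math.radians(gamma)
        direction = (-math.cos(rad), rear_sign * math.sin(rad))
        count = segment_overlap(knee, direction, model.kh_dist, region.bits)
        if count > best_count:
            best_gamma, best_count = gamma, count
    if best_gamma is None:
        raise TrackingError("no rotating-vector overlap for the hip")
    rad = math.radians(best_gamma)
    return _segment_end(knee, (-math.cos(rad), rear_sign * math.sin(rad)),
                        model.kh_dist)


# ---------------------------------------------------------------------------
# per-frame orchestration and trajectories
# ---------------------------------------------------------------------------

@dataclass
class JointSet:
    """Six located joints for one frame; ``None`` marks a failed locator."""

    frame_index: int
    coords: dict[str, Optional[PixelCoord]] = field(default_factory=dict)

    def __getitem__(self, joint: str) -> Optional[PixelCoord]:
        return self.coords.get(joint)


@dataclass
class Trajectory:
    """Per-joint ordered pixel coordinates over a sequence.

    Coordinates are ``(row, col)`` tuples (floats allowed, e.g. after
    offset compensation); ``None`` marks a missing frame for that joint.
    """

    joints: dict[str, list[Optional[tuple[float, float]]]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.joints.values()}
        if len(lengths) > 1:
            raise ValueError("joint tracks have differing lengths")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.joints.values()))) if self.joints else 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for joint, track in self.joints.items():
            for k, pt in enumerate(track):
                if pt is None:
                    rows.append((k, joint, 0.0, 0.0, 1))
                else:
                    rows.append((k, joint, float(pt[0]), float(pt[1]), 0))
        frame = pd.DataFrame(rows,
                             columns=["frame", "joint", "row", "col",
                                      "missing"])
        return frame.sort_values(["frame", "joint"],
                                 kind="stable").reset_index(drop=True)

    def save_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "Trajectory":
        frame = pd.read_csv(path)
        required = {"frame", "joint", "row", "col", "missing"}
        if not required.issubset(frame.columns):
            raise ValueError(f"trajectory CSV needs columns {sorted(required)}")
        n = int(frame["frame"].max()) + 1 if len(frame) else 0
        joints: dict[str, list[Optional[tuple[float, float]]]] = {}
        for joint, grp in frame.groupby("joint"):
            track: list[Optional[tuple[float, float]]] = [None] * n
            for _, rec in grp.iterrows():
                if not int(rec["missing"]):
                    track[int(rec["frame"])] = (float(rec["row"]),
                                                float(rec["col"]))
            joints[str(joint)] = track
        return cls(joints=joints)

    def interpolated(self) -> "Trajectory":
        """Linear interpolation across missing frames (plotting aid only)."""
        out: dict[str, list[Optional[tuple[float, float]]]] = {}
        for joint, track in self.joints.items():
            idx = [k for k, p in enumerate(track) if p is not None]
            if not idx:
                out[joint] = list(track)
                continue
            ks = np.arange(len(track))
            rows = np.interp(ks, idx, [track[k][0] for k in idx])
            cols = np.interp(ks, idx, [track[k][1] for k in idx])
            out[joint] = [(float(r), float(c)) for r, c in zip(rows, cols)]
        return Trajectory(joints=out)


def track_frame(df: np.ndarray, bf: np.ndarray, model: BodyModel,
                intr: IntrinsicModel = DEFAULT_INTRINSICS,
                th: int = DEFAULT_FOREGROUND_THRESHOLD_MM,
                frame_index: int = 0, rear_sign: int = 1) -> JointSet:
    """Locate the six side-view joints on a single depth frame.

    Locator failures (including failures of a joint they depend on) yield
    ``None`` for that joint rather than aborting the frame.
    """
    coords: dict[str, Optional[PixelCoord]] = {j: None for j in JOINT_NAMES}
    js = JointSet(frame_index=frame_index, coords=coords)
    df = as_depth_frame(df)
    try:
        sil = largest_silhouette(foreground_mask(df, bf, th))
    except NoSubjectError:
        return js
    depths = df[sil.bits]
    depths = depths[depths > 0]
    if depths.size == 0:
        return js
    frame_depth = float(np.median(depths))

    try:
        coords["head"] = locate_head_side(sil, model)
        coords["shoulder"] = locate_shoulder_side(sil, coords["head"], model)
    except TrackingError:
        pass
    if coords["shoulder"] is not None:
        try:
            coords["elbow"] = locate_elbow_side(df, sil, coords["shoulder"],
                                                model)
        except TrackingError:
            pass
    try:
        region = near_side_region(df, sil, model)
    except TrackingError:
        return js
    try:
        coords["ankle"] = locate_ankle_side(region, sil, model, frame_depth,
                                            intr)
        coords["knee"] = locate_knee_side(region, coords["ankle"], model)
        coords["hip"] = locate_hip_side(region, coords["knee"], model,
                                        rear_sign=rear_sign)
    except TrackingError:
        pass
    return js


def track_sequence(seq: FrameSequence, bf: np.ndarray, model: BodyModel,
                   intr: IntrinsicModel = DEFAULT_INTRINSICS,
                   th: int = DEFAULT_FOREGROUND_THRESHOLD_MM,
                   rear_sign: int = 1) -> Trajectory:
    """Track all six joints over a sequence, independently per frame."""
    tracks: dict[str, list[Optional[tuple[float, float]]]] = {
        j: [] for j in JOINT_NAMES}
    for k, df in enumerate(seq):
        js = track_frame(df, bf, model, intr, th, frame_index=k,
                         rear_sign=rear_sign)
        for j in JOINT_NAMES:
            pt = js[j]
            tracks[j].append(None if pt is None
                             else (float(pt.row), float(pt.col)))
    return Trajectory(joints=tracks)
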