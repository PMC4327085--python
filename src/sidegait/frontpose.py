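"""Front-plane pose analysis: anthropometric joint localization and the
per-subject calibration used by the side-view tracker.

The subject stands facing the sensor at roughly 3 m with arms held out and
away from the torso.  A single depth frame is segmented and scanned with
anthropometric rules (head/stature ratio, hip coefficient, ankle-knee
fraction) to produce pixel coordinates for seven joints and the five
inter-joint distances stored in the :class:`BodyModel`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import yaml

from .background import (DEFAULT_FOREGROUND_THRESHOLD_MM, Silhouette,
                         foreground_mask, largest_silhouette)
from .depth_core import (DEFAULT_INTRINSICS, IntrinsicModel, PixelCoord,
                         as_depth_frame, metric_to_pixels, round_half_up)
from .errors import CalibrationError, PoseError

#: Vertical scan step while looking for the shoulder widening (mm).
SCAN_STEP_MM = 40
#: Offset below the top of the head where the scan starts (mm).
SCAN_START_OFFSET_MM = 100
#: Modelled neck height (mm), subtracted when measuring the head.
NECK_HEIGHT_MM = 100
#: Shoulder shifts below the widening row and in from the arm edge (mm).
SHOULDER_SHIFT_MM = 40
#: Upward offset of the ankle row from the bottom of the silhouette (mm).
ANKLE_OFFSET_MM = 40
#: Ankle-knee distance as a fraction of total body height.
ANKLE_KNEE_FRACTION = 0.2

#: Hip-coefficient lookup: ``c`` for increasing ranges of the ratio R
#: (stature / head height).  Upper branches are left-closed.
_C_BRANCHES = ((6.4, 3.2), (7.2, 3.4), (7.5, 3.6), (8.0, 3.8), (8.8, 4.0))
_C_TOP = 4.2


@dataclass
class BodyModel:
    """Calibrated per-subject quantities, pixel units unless noted."""

    human_height: int
    head_height: int
    shift_row: int
    c: float
    R: float
    hs_dist: int
    se_dist: int
    ew_dist: int
    ak_dist: int
    kh_dist: int
    subject_depth: float  # mm

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "BodyModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class FrontPoseJoints:
    """Joint coordinates located on the front-plane pose frame."""

    head: PixelCoord
    shoulder: PixelCoord
    elbow: PixelCoord
    wrist: PixelCoord
    hip: PixelCoord
    knee: PixelCoord
    ankle: PixelCoord

    def items(self):
        return [("head", self.head), ("shoulder", self.shoulder),
                ("elbow", self.elbow), ("wrist", self.wrist),
                ("hip", self.hip), ("knee", self.knee),
                ("ankle", self.ankle)]


def human_height(sil: Silhouette) -> int:
    """Pixel height of the silhouette: bottom row minus top row."""
    return sil.last_row - sil.first_row


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def table1_ratio(stature_cm: float, head_height_cm: float) -> float:
    """Stature / head-height ratio R, reported to 2 decimals."""
    if stature_cm <= 0 or head_height_cm <= 0:
        raise ValueError("stature and head height must be positive")
    return _round2(stature_cm / head_height_cm)


def table1_coefficient(stature_cm: float, buttock_height_cm: float,
                       head_height_cm: float) -> float:
    """Empirical hip coefficient (stature - buttock height) / head height."""
    if not stature_cm > buttock_height_cm > 0:
        raise ValueError("need stature > buttock height > 0")
    if head_height_cm <= 0:
        raise ValueError("head height must be positive")
    return _round2((stature_cm - buttock_height_cm) / head_height_cm)


def coefficient_c(R: float) -> float:
    """Piecewise-constant hip coefficient as a function of the ratio R."""
    if R <= 0:
        raise ValueError("R must be positive")
    for upper, c in _C_BRANCHES:
        if R < upper:
            return c
    return _C_TOP


def find_row_max_dim(sil: Silhouette, depth_mm: float,
                     intr: IntrinsicModel = DEFAULT_INTRINSICS,
                     step_mm: float = SCAN_STEP_MM,
                     start_offset_mm: float = SCAN_START_OFFSET_MM) -> int:
    """Row of the maximal width increase: the top of the shoulders.

    Rows are sampled every ``step_mm`` starting ``start_offset_mm`` below
    the top of the silhouette, until the scanned span reaches one third of
    the silhouette height.  The sampled row whose silhouette width grows
    the most over the previous sample is returned (earliest on ties).
    """
    start_px = metric_to_pixels(start_offset_mm, depth_mm, intr, "rows")
    step_px = max(1, metric_to_pixels(step_mm, depth_mm, intr, "rows"))
    start_row = sil.first_row + start_px
    limit = human_height(sil) // 3
    rows = []
    r = start_row
    while r - start_row <= limit and r <= sil.last_row:
        rows.append(r)
        r += step_px
    if len(rows) < 2:
        raise CalibrationError("silhouette too short for the shoulder scan")
    widths = np.array([len(sil.row_cols(r)) for r in rows])
    diffs = np.concatenate([[0], np.diff(widths)])
    return rows[int(np.argmax(diffs))]


def locate_head_front(sil: Silhouette,
                      row_max_dim: int) -> tuple[PixelCoord, int]:
    """Head joint and the row shift reused later in side view.

    The shift is a third of the distance between the silhouette top and the
    shoulder widening row; the head column is the midpoint of the first and
    last silhouette columns on the head row.
    """
    if row_max_dim <= sil.first_row:
        raise CalibrationError("shoulder row not below silhouette top")
    shift_row = (row_max_dim - sil.first_row) // 3
    head_row = sil.first_row + shift_row
    cols = sil.row_cols(head_row)
    if cols.size == 0:
        raise CalibrationError(f"no silhouette pixels on head row {head_row}")
    head_col = round_half_up((int(cols[0]) + int(cols[-1])) / 2)
    return PixelCoord(head_row, head_col), shift_row


def head_height(sil: Silhouette, row_max_dim: int, depth_mm: float,
                intr: IntrinsicModel = DEFAULT_INTRINSICS,
                neck_mm: float = NECK_HEIGHT_MM) -> int:
    """Pixel head height: top-to-shoulder span minus the neck allowance."""
    neck_px = metric_to_pixels(neck_mm, depth_mm, intr, "rows")
    hh = (row_max_dim - sil.first_row) - neck_px
    if hh <= 0:
        raise CalibrationError("head height non-positive; bad shoulder row")
    return hh


def locate_shoulder_front(sil: Silhouette, row_max_dim: int, depth_mm: float,
                          intr: IntrinsicModel = DEFAULT_INTRINSICS,
                          arm_side: str = "left") -> PixelCoord:
    """Shoulder joint 40 mm below the widening row, 40 mm in from the edge."""
    row = row_max_dim + metric_to_pixels(SHOULDER_SHIFT_MM, depth_mm, intr,
                                         "rows")
    cols = sil.row_cols(row)
    if cols.size == 0:
        raise CalibrationError(f"no silhouette pixels on shoulder row {row}")
    shift = metric_to_pixels(SHOULDER_SHIFT_MM, depth_mm, intr, "cols")
    col = int(cols[0]) + shift if arm_side == "left" else int(cols[-1]) - shift
    if not (0 <= col < sil.bits.shape[1]) or not sil.bits[row, col]:
        raise CalibrationError("shoulder shift landed outside the silhouette")
    return PixelCoord(row, col)


def locate_hip_row(sil: Silhouette, head_height_px: int, c: float) -> int:
    """Hip row: ``c`` head heights below the top of the silhouette."""
    row = sil.first_row + round_half_up(c * head_height_px)
    if row > sil.last_row:
        raise CalibrationError("hip row falls below the silhouette")
    return row


def _runs(cols: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, end] column runs of a sorted index array."""
    if cols.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(cols) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [cols.size - 1]])
    return [(int(cols[s]), int(cols[e])) for s, e in zip(starts, ends)]


def torso_center_col(sil: Silhouette, row: int) -> int:
    """Column midpoint of the widest contiguous silhouette run on ``row``."""
    runs = _runs(sil.row_cols(row))
    if not runs:
        raise CalibrationError(f"no silhouette pixels on row {row}")
    start, end = max(runs, key=lambda r: r[1] - r[0])
    return round_half_up((start + end) / 2)


def locate_ankle_and_knee_front(
        sil: Silhouette, human_height_px: int, depth_mm: float,
        intr: IntrinsicModel = DEFAULT_INTRINSICS,
) -> tuple[PixelCoord, PixelCoord, int]:
    """Ankle 40 mm above the silhouette bottom; knee one ankle-knee
    distance (0.2 x body height) above it.  Columns are silhouette means."""
    ankle_row = sil.last_row - metric_to_pixels(ANKLE_OFFSET_MM, depth_mm,
                                                intr, "rows")
    cols = sil.row_cols(ankle_row)
    if cols.size == 0:
        raise CalibrationError(f"no silhouette pixels on ankle row")
    ankle = PixelCoord(ankle_row, round_half_up(float(cols.mean())))
    ak_dist = round_half_up(ANKLE_KNEE_FRACTION * human_height_px)
    knee_row = ankle_row - ak_dist
    kcols = sil.row_cols(knee_row)
    if kcols.size == 0:
        raise CalibrationError(f"no silhouette pixels on knee row")
    knee = PixelCoord(knee_row, round_half_up(float(kcols.mean())))
    return ankle, knee, ak_dist


def locate_arm_chain(sil: Silhouette, hip_row: int, head_height_px: int,
                     shoulder: PixelCoord,
                     arm_side: str = "left") -> tuple[PixelCoord, PixelCoord]:
    """Wrist and elbow from the arm separated from the torso on the hip row.

    Requires a column gap between arm and body on the hip row (the
    outstretched-arm pose); the wrist sits half a head height above the
    lowest arm pixel and the elbow is the wrist-shoulder midpoint.
    """
    runs = _runs(sil.row_cols(hip_row))
    if len(runs) < 2:
        raise PoseError("no arm-body gap on the hip row; arms not held out")
    if arm_side == "left":
        arm_cols = slice(0, runs[0][1] + 1)
        sub = sil.bits[:, arm_cols]
        col_offset = 0
    else:
        sub = sil.bits[:, runs[-1][0]:]
        col_offset = runs[-1][0]
    rows = np.flatnonzero(sub.any(axis=1))
    if rows.size == 0:
        raise PoseError("empty arm sub-region")
    arm_end_row = int(rows[-1])
    wrist_row = arm_end_row - head_height_px // 2
    wcols = np.flatnonzero(sub[wrist_row]) if 0 <= wrist_row < sub.shape[0] \
        else np.empty(0, dtype=int)
    if wcols.size == 0:
        raise PoseError(f"no arm pixels on wrist row {wrist_row}")
    wrist = PixelCoord(wrist_row,
                       col_offset + round_half_up(float(wcols.mean())))
    elbow = PixelCoord(round_half_up((wrist.row + shoulder.row) / 2),
                       round_half_up((wrist.col + shoulder.col) / 2))
    return wrist, elbow


def calibrate(df: np.ndarray, bf: np.ndarray,
              intr: IntrinsicModel = DEFAULT_INTRINSICS,
              th: int = DEFAULT_FOREGROUND_THRESHOLD_MM,
              arm_side: str = "left") -> tuple[BodyModel, FrontPoseJoints]:
    """Run the full front-plane chain on one depth frame.

    Returns the calibrated :class:`BodyModel` (pixel distances between the
    located joints, hip coefficient and subject depth) together with the
    joint coordinates themselves.
    """
    df = as_depth_frame(df)
    mask = foreground_mask(df, bf, th)
    sil = largest_silhouette(mask)
    depths = df[sil.bits]
    depths = depths[depths > 0]
    if depths.size == 0:
        raise CalibrationError("silhouette has no valid depth readings")
    subject_depth = float(np.median(depths))

    hh_total = human_height(sil)
    row_max_dim = find_row_max_dim(sil, subject_depth, intr)
    head, shift_row = locate_head_front(sil, row_max_dim)
    hh_px = head_height(sil, row_max_dim, subject_depth, intr)
    shoulder = locate_shoulder_front(sil, row_max_dim, subject_depth, intr,
                                     arm_side)
    R = hh_total / hh_px
    c = coefficient_c(R)
    hip_row = locate_hip_row(sil, hh_px, c)
    hip = PixelCoord(hip_row, torso_center_col(sil, hip_row))
    ankle, knee, ak_dist = locate_ankle_and_knee_front(
        sil, hh_total, subject_depth, intr)
    wrist, elbow = locate_arm_chain(sil, hip_row, hh_px, shoulder, arm_side)

    model = BodyModel(
        human_height=hh_total,
        head_height=hh_px,
        shift_row=shift_row,
        c=c,
        R=R,
        hs_dist=max(1, round_half_up(head.distance_to(shoulder))),
        se_dist=max(1, round_half_up(shoulder.distance_to(elbow))),
        ew_dist=max(1, round_half_up(elbow.distance_to(wrist))),
        ak_dist=ak_dist,
        kh_dist=max(1, round_half_up(knee.distance_to(hip))),
        subject_depth=subject_depth,
    )
    joints = FrontPoseJoints(head=head, shoulder=shoulder, elbow=elbow,
                             wrist=wrist, hip=hip, knee=knee, ankle=ankle)
    return model, joints
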