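"""Trajectory validation against reference (marker or synthetic) tracks.

Per joint and frame the Euclidean pixel difference is computed; frames
where either track is missing (marker occlusion, locator failure) are
excluded from the mean/standard-deviation summaries.  A constant per-joint
offset can be removed first via a least-squares fit, which for a pure
translation reduces to the mean coordinate difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage import measure

from .depth_core import PixelCoord
from .errors import ValidationError
from .sideview import JOINT_NAMES, Trajectory

#: A reference track has the same shape as an estimated trajectory.
ReferenceTrack = Trajectory


@dataclass
class DiffSeries:
    """Per-frame joint differences with occlusion-aware summaries.

    ``values`` holds one entry per frame (``None`` where either track was
    missing); ``mu``/``sigma`` are computed over the present entries only,
    ``sigma`` with the n-1 (sample) convention.
    """

    values: list[Optional[float]]
    mu: float
    sigma: float
    n_valid: int

    @property
    def evaluable(self) -> bool:
        return self.n_valid > 0


def joint_difference(est: Optional[tuple[float, float] | PixelCoord],
                     ref: Optional[tuple[float, float] | PixelCoord],
                     ) -> Optional[float]:
    """Euclidean pixel distance between two joint positions.

    Returns ``None`` (missing propagated) when either input is missing.
    """
    if est is None or ref is None:
        return None
    er, ec = (est.row, est.col) if isinstance(est, PixelCoord) else est
    rr, rc = (ref.row, ref.col) if isinstance(ref, PixelCoord) else ref
    return math.hypot(er - rr, ec - rc)


def compensate_offset(traj: Trajectory, ref: ReferenceTrack) -> Trajectory:
    """Remove the constant per-joint offset between the two tracks.

    The offset minimizing the sum of squared coordinate differences over
    jointly present frames is their mean difference; it is added to the
    estimated track.  Missing frames are preserved.
    """
    if traj.n_frames != ref.n_frames:
        raise ValidationError("trajectories have different lengths")
    out: dict[str, list[Optional[tuple[float, float]]]] = {}
    for joint, track in traj.joints.items():
        rtrack = ref.joints.get(joint)
        if rtrack is None:
            out[joint] = list(track)
            continue
        both = [(e, r) for e, r in zip(track, rtrack)
                if e is not None and r is not None]
        if not both:
            raise ValidationError(f"no overlapping frames for joint {joint!r}")
        dr = float(np.mean([r[0] - e[0] for e, r in both]))
        dc = float(np.mean([r[1] - e[1] for e, r in both]))
        out[joint] = [None if e is None else (e[0] + dr, e[1] + dc)
                      for e in track]
    return Trajectory(joints=out)


def diff_statistics(traj: Trajectory, ref: ReferenceTrack,
                    compensate: bool = False) -> dict[str, DiffSeries]:
    """Per-joint difference series and mu/sigma summaries.

    Occluded/missing frames carry ``None`` in the series and are excluded
    from the statistics; a joint with no jointly present frame is returned
    with ``n_valid`` 0 (not evaluable).
    """
    if traj.n_frames != ref.n_frames:
        raise ValidationError("trajectories have different lengths")
    if compensate:
        traj = compensate_offset(traj, ref)
    result: dict[str, DiffSeries] = {}
    for joint, track in traj.joints.items():
        rtrack = ref.joints.get(joint, [None] * traj.n_frames)
        values = [joint_difference(e, r) for e, r in zip(track, rtrack)]
        present = np.array([v for v in values if v is not None])
        if present.size == 0:
            result[joint] = DiffSeries(values=values, mu=float("nan"),
                                       sigma=float("nan"), n_valid=0)
            continue
        mu = float(present.mean())
        sigma = float(present.std(ddof=1)) if present.size > 1 else 0.0
        result[joint] = DiffSeries(values=values, mu=mu, sigma=sigma,
                                   n_valid=int(present.size))
    return result


def statistics_table(stats: dict[str, DiffSeries]) -> pd.DataFrame:
    """mu/sigma summary as a table, joints in head..ankle order."""
    order = [j for j in JOINT_NAMES if j in stats]
    order += [j for j in stats if j not in order]
    return pd.DataFrame(
        {"joint": order,
         "mu": [stats[j].mu for j in order],
         "sigma": [stats[j].sigma for j in order],
         "n": [stats[j].n_valid for j in order]})


def save_diff_series(stats: dict[str, DiffSeries], path: str | Path) -> None:
    """Write per-frame difference curves; occluded frames as 0 + flag."""
    rows = []
    for joint, series in stats.items():
        for k, v in enumerate(series.values):
            rows.append((k, joint, 0.0 if v is None else v,
                         1 if v is None else 0))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["frame", "joint", "d", "occluded"]).to_csv(
        path, index=False)


def detect_markers(ir_frame: np.ndarray, intensity_threshold: float,
                   expected_count: int = 6,
                   ) -> list[Optional[PixelCoord]]:
    """Centroids of bright marker blobs, assigned to joints top-to-bottom.

    Returns ``expected_count`` entries; when fewer blobs are found the
    trailing joints are reported occluded (``None``).
    """
    img = np.asarray(ir_frame, dtype=float)
    labels = measure.label(img >= intensity_threshold, connectivity=2)
    centroids = []
    for region in measure.regionprops(labels):
        r, c = region.centroid
        centroids.append(PixelCoord(round(r), round(c)))
    centroids.sort(key=lambda p: (p.row, p.col))
    if len(centroids) > expected_count:
        centroids = centroids[:expected_count]
    out: list[Optional[PixelCoord]] = list(centroids)
    out += [None] * (expected_count - len(out))
    return out
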