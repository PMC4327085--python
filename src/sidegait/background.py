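"""Reference background construction and silhouette segmentation.

The subject is isolated by thresholded background subtraction: a pixel is
foreground when its depth differs from the background frame by at least the
threshold (default 150 mm), and the silhouette is the largest 8-connected
foreground component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import measure

from .depth_core import FrameSequence, as_depth_frame
from .errors import NoSubjectError

#: Depth threshold separating subject from background (mm).
DEFAULT_FOREGROUND_THRESHOLD_MM = 150


def build_background(frames: FrameSequence) -> np.ndarray:
    """Per-pixel temporal mean of the empty scene over valid readings.

    Invalid (zero) readings are excluded from the mean; a pixel with no
    valid reading in any frame stays 0.  Result is rounded to integer mm.
    """
    if len(frames) == 0:
        raise ValueError("background needs at least one frame")
    stack = np.stack([as_depth_frame(f) for f in frames]).astype(np.float64)
    valid = stack > 0
    count = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return np.floor(mean + 0.5).astype(np.int32)


def foreground_mask(df: np.ndarray, bf: np.ndarray,
                    th: int = DEFAULT_FOREGROUND_THRESHOLD_MM) -> np.ndarray:
    """Binary foreground map: 1 where ``|DF - BF| >= th``, else 0.

    Pixels with no depth reading (DF == 0) are never foreground.
    """
    df = as_depth_frame(df)
    bf = as_depth_frame(bf)
    if df.shape != bf.shape:
        raise ValueError(f"shape mismatch: {df.shape} vs {bf.shape}")
    if th <= 0:
        raise ValueError("threshold must be positive")
    mask = (np.abs(df.astype(np.int64) - bf.astype(np.int64)) >= th)
    mask &= df > 0
    return mask.astype(np.uint8)


@dataclass
class Silhouette:
    """Largest connected foreground component with its tight bounding box."""

    bits: np.ndarray
    first_row: int
    last_row: int
    first_col: int
    last_col: int

    @property
    def height(self) -> int:
        return self.last_row - self.first_row

    def row_cols(self, row: int) -> np.ndarray:
        """Column indices of silhouette pixels on ``row`` (may be empty)."""
        if row < 0 or row >= self.bits.shape[0]:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.bits[row])


def largest_silhouette(mask: np.ndarray) -> Silhouette:
    """Select the 8-connected component of maximal pixel count.

    Size ties go to the component whose first pixel comes first in
    row-major scan order.
    """
    mask = np.asarray(mask)
    if mask.sum() == 0:
        raise NoSubjectError("foreground mask is empty")
    labels = measure.label(mask > 0, connectivity=2)
    flat = labels.ravel()
    counts = np.bincount(flat)
    counts[0] = 0
    best_size = counts.max()
    tied = np.flatnonzero(counts == best_size)
    if len(tied) == 1:
        lab = tied[0]
    else:
        # earliest first-pixel in row-major order wins
        lab = min(tied, key=lambda lb: int(np.flatnonzero(flat == lb)[0]))
    bits = (labels == lab)
    rows, cols = np.nonzero(bits)
    return Silhouette(
        bits=bits,
        first_row=int(rows.min()), last_row=int(rows.max()),
        first_col=int(cols.min()), last_col=int(cols.max()),
    )


def export_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG for visual inspection."""
    img = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), img)
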