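"""Depth-frame data model, file I/O and the pinhole metric<->pixel conversion.

A depth frame is a 2-D integer array of per-pixel distances in millimetres;
the value 0 encodes "no reading".  Row 0 is the top of the image and all
coordinates are 0-based ``(row, col)`` pairs.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InvalidDepthError

#: Native frame size of the depth stream (rows, cols).
FRAME_SHAPE = (240, 320)

RAW_MAGIC = b"DSEQ"

Axis = Literal["rows", "cols"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (away from floor)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class IntrinsicModel:
    """Pinhole intrinsics of the depth camera (all in pixels)."""

    focal_x: float = 285.6
    focal_y: float = 285.6
    center_x: float = 159.5
    center_y: float = 119.75

    def __post_init__(self) -> None:
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")

    def focal(self, axis: Axis) -> float:
        return self.focal_y if axis == "rows" else self.focal_x


#: Canonical Kinect-v1 intrinsics halved to the 320x240 stream resolution.
DEFAULT_INTRINSICS = IntrinsicModel()


@dataclass(frozen=True)
class PixelCoord:
    """0-based image coordinate; ``row`` 0 is the top of the frame."""

    row: int
    col: int

    def distance_to(self, other: "PixelCoord") -> float:
        return math.hypot(self.row - other.row, self.col - other.col)

    def as_tuple(self) -> tuple[int, int]:
        return (self.row, self.col)


def as_depth_frame(values: np.ndarray) -> np.ndarray:
    """Validate and canonicalise a depth frame to an int32 mm array."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise FormatError(f"depth frame must be 2-D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.rint(arr)
    arr = arr.astype(np.int32, copy=False)
    if (arr < 0).any():
        raise FormatError("depth values must be >= 0")
    return arr


@dataclass
class FrameSequence:
    """Ordered stack of equally shaped depth frames."""

    frames: list[np.ndarray]
    timestamps: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = [as_depth_frame(f) for f in self.frames]
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape if self.frames else FRAME_SHAPE


# ---------------------------------------------------------------------------
# metric <-> pixel conversion (pinhole model)
# ---------------------------------------------------------------------------

def metric_to_pixels(length_mm: float, depth_mm: float,
                     intr: IntrinsicModel = DEFAULT_INTRINSICS,
                     axis: Axis = "rows") -> int:
    """Convert a physical length at a given depth into a pixel count.

    Uses the pinhole relation ``round(length * focal / depth)`` with the
    axis-matched focal length; the result is monotone in ``length_mm``.
    """
    if depth_mm <= 0:
        raise InvalidDepthError(f"depth must be positive, got {depth_mm}")
    return round_half_up(abs(length_mm) * intr.focal(axis) / depth_mm)


def pixels_to_metric(pixels: float, depth_mm: float,
                     intr: IntrinsicModel = DEFAULT_INTRINSICS,
                     axis: Axis = "rows") -> float:
    """Inverse of :func:`metric_to_pixels` (exact, no rounding)."""
    if depth_mm <= 0:
        raise InvalidDepthError(f"depth must be positive, got {depth_mm}")
    return pixels * depth_mm / intr.focal(axis)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

Dialect = Literal["pgm16-stack", "png16-stack", "raw"]

_STACK_EXT = {"pgm16-stack": ".pgm", "png16-stack": ".png"}


def _to_uint16(frame: np.ndarray) -> np.ndarray:
    arr = as_depth_frame(frame)
    if (arr > 0xFFFF).any():
        raise FormatError("depth value exceeds 16-bit range")
    return arr.astype(np.uint16)


def save_depth_sequence(seq: FrameSequence | Iterable[np.ndarray],
                        path: str | Path,
                        dialect: Dialect = "png16-stack") -> None:
    """Write a sequence to disk in one of the supported dialects.

    Stack dialects write one 16-bit image per frame under a directory with
    zero-padded numeric names; ``raw`` writes a single headered binary file.
    """
    frames = list(seq.frames if isinstance(seq, FrameSequence) else seq)
    frames = [_to_uint16(f) for f in frames]
    path = Path(path)
    if dialect == "raw":
        if not frames:
            raise FormatError("cannot write an empty raw sequence")
        h, w = frames[0].shape
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            fh.write(RAW_MAGIC)
            fh.write(struct.pack("<III", w, h, len(frames)))
            for f in frames:
                fh.write(f.astype("<u2").tobytes())
        return
    if dialect not in _STACK_EXT:
        raise FormatError(f"unknown dialect {dialect!r}")
    ext = _STACK_EXT[dialect]
    path.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        iio.imwrite(path / f"frame_{i:05d}{ext}", f)


def load_depth_sequence(path: str | Path,
                        dialect: Dialect = "png16-stack") -> FrameSequence:
    """Read a sequence written by :func:`save_depth_sequence`.

    Frames are returned in capture order (zero-padded suffix order for the
    stack dialects).  Unreadable pixels are already encoded as 0 on disk.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "raw":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != RAW_MAGIC:
                raise FormatError(f"bad raw magic {magic!r}")
            w, h, n = struct.unpack("<III", fh.read(12))
            data = np.frombuffer(fh.read(), dtype="<u2")
        if data.size != w * h * n:
            raise FormatError("raw payload size does not match header")
        return FrameSequence(list(data.reshape(n, h, w)))
    if dialect not in _STACK_EXT:
        raise FormatError(f"unknown dialect {dialect!r}")
    files = sorted(path.glob(f"*{_STACK_EXT[dialect]}"))
    if not files:
        raise FileNotFoundError(f"no {_STACK_EXT[dialect]} files under {path}")
    frames = [np.asarray(iio.imread(f)) for f in files]
    return FrameSequence(frames)
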