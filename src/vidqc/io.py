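"""Frame streams, per-frame timestamp tables, and recording-length conventions.

Two recording-length conventions coexist and are both exposed:

* timestamped acquisition streams: length = onset of the
  very last frame, because the last offset is stored as an unbounded
  sentinel rather than a real number;
* plain container videos: length = frame_count / nominal_fps.

Timestamp tables are CSV with header ``frame_index,onset_s,offset_s``; the
literal token ``inf`` is permitted in the final offset and maps to the
UNBOUNDED sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _avi

#: Sentinel for an offset the acquisition system never closed (stored as
#: literal ``inf`` on disk, mirroring how such systems serialise it).
UNBOUNDED = math.inf

LIGHTING_CONDITIONS = frozenset({"no_light", "cue", "red", "white", "white_cue"})


class EmptyStreamError(ValueError):
    """A video yielded zero decodable frames."""


class DegenerateRecordingError(ValueError):
    """Timestamp table too short to define a recording length."""


class TimestampValidationError(ValueError):
    """Timestamp table violates monotonicity/contiguity, with the row named."""


@dataclass
class FrameStream:
    """Ordered sequence of 8-bit frames plus the container's nominal rate.

    ``frames`` is a single uint8 array, shape (F, H, W) for grayscale or
    (F, H, W, 3) for RGB color.
    """

    frames: np.ndarray
    nominal_fps: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (F, H, W) or (F, H, W, 3)")
        if self.frames.ndim == 4 and self.frames.shape[3] != 3:
            raise ValueError("color frames must have exactly 3 channels")
        if not self.nominal_fps > 0:
            raise ValueError("nominal_fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition set point and lighting condition for one recording."""

    target_fps: float
    lighting: str = "white"
    source_label: str = ""

    def __post_init__(self):
        if not self.target_fps > 0:
            raise ValueError("target_fps must be positive")
        if self.lighting not in LIGHTING_CONDITIONS:
            raise ValueError(
                f"lighting {self.lighting!r} not in {sorted(LIGHTING_CONDITIONS)}"
            )


@dataclass
class TimestampTable:
    """Per-frame (frame_index, onset_s, offset_s) records.

    Indices are 0-based and contiguous; onsets non-decreasing; offsets are
    finite and >= onset except possibly the last, which may be UNBOUNDED.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        required = ["frame_index", "onset_s", "offset_s"]
        if list(df.columns[:3]) != required:
            raise TimestampValidationError(
                f"expected columns {required}, got {list(df.columns)}"
            )
        idx = df["frame_index"].to_numpy()
        onsets = df["onset_s"].to_numpy(dtype=float)
        offsets = df["offset_s"].to_numpy(dtype=float)
        if len(df) and not np.array_equal(idx, np.arange(len(df))):
            bad = int(np.flatnonzero(idx != np.arange(len(df)))[0])
            raise TimestampValidationError(
                f"frame_index not contiguous from 0 at row {bad}"
            )
        if len(df) > 1:
            steps = np.diff(onsets)
            if np.any(steps < 0):
                bad = int(np.flatnonzero(steps < 0)[0]) + 1
                raise TimestampValidationError(
                    f"onset_s decreases at row {bad} "
                    f"({onsets[bad - 1]:g} -> {onsets[bad]:g})"
                )
        if np.any(onsets < 0):
            bad = int(np.flatnonzero(onsets < 0)[0])
            raise TimestampValidationError(f"negative onset at row {bad}")
        finite = np.isfinite(offsets)
        if np.any(~finite[:-1] if len(df) else []):
            bad = int(np.flatnonzero(~finite[:-1])[0])
            raise TimestampValidationError(
                f"UNBOUNDED offset permitted only on the last row, found at row {bad}"
            )
        if np.any(offsets[finite] < onsets[finite]):
            bad = int(np.flatnonzero(finite)[np.flatnonzero(offsets[finite] < onsets[finite])[0]])
            raise TimestampValidationError(f"offset < onset at row {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset_s"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, onsets, offsets=None) -> "TimestampTable":
        onsets = np.asarray(onsets, dtype=float)
        if offsets is None:
            offsets = np.append(onsets[1:], UNBOUNDED)
        return cls(
            pd.DataFrame(
                {
                    "frame_index": np.arange(len(onsets)),
                    "onset_s": onsets,
                    "offset_s": np.asarray(offsets, dtype=float),
                }
            )
        )


def read_video(path) -> FrameStream:
    """Decode every frame of a video container, in order, as RGB/grayscale.

    AVI (uncompressed DIB profile) is decoded natively.  Other containers
    are attempted through :mod:`imageio` if an ffmpeg-capable plugin is
    installed; without one, a clear error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".avi":
        frames, fps = _avi.read_avi(path)
    else:
        try:
            import imageio.v3 as iio

            frames = np.asarray(iio.imread(path, plugin="pyav"))
            fps = float(iio.immeta(path, plugin="pyav").get("fps", 0.0))
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise IOError(
                f"cannot decode {path}: no multimedia backend for "
                f"{path.suffix} containers is installed (AVI is always supported)"
            ) from exc
    if frames.shape[0] == 0:
        raise EmptyStreamError(f"{path}: zero decodable frames")
    return FrameStream(frames, nominal_fps=fps if fps > 0 else 1.0)


def write_video(stream: FrameStream, path) -> None:
    """Write a frame stream as an uncompressed (lossless) AVI."""
    path = Path(path)
    if path.suffix.lower() != ".avi":
        raise ValueError(
            f"only the built-in uncompressed AVI writer is available; got {path.suffix}"
        )
    _avi.write_avi(path, stream.frames, stream.nominal_fps)


def read_timestamp_table(path) -> TimestampTable:
    """Read and validate a ``frame_index,onset_s,offset_s`` CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    # pandas parses the literal token "inf" to float inf already
    df["frame_index"] = df["frame_index"].astype(int)
    return TimestampTable(df[["frame_index", "onset_s", "offset_s"]].astype(
        {"onset_s": float, "offset_s": float}
    ))


def write_timestamp_table(table: TimestampTable, path) -> None:
    df = table.frame.copy()
    df["offset_s"] = df["offset_s"].map(
        lambda v: "inf" if math.isinf(v) else repr(float(v))
    )
    df["onset_s"] = df["onset_s"].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)


def recording_length(table: TimestampTable) -> float:
    """Recording length under the timestamped-stream convention.

    The onset of the very last frame is taken as the recording length (the
    final offset is unbounded and unusable).
    """
    if len(table) < 2:
        raise DegenerateRecordingError(
            f"need >= 2 timestamp rows to define a recording length, got {len(table)}"
        )
    return float(table.onsets[-1])


def container_length(stream: FrameStream) -> float:
    """Recording length under the container convention: frames / nominal fps."""
    if len(stream) == 0:
        raise EmptyStreamError("empty stream has no container length")
    return len(stream) / stream.nominal_fps
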