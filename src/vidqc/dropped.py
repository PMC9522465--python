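"""Dropped-frame accounting from per-frame timestamps.

Given the per-frame onset timestamps and the acquisition set point
(target FPS), four quantities describe how badly a camera fell short:

    true FPS            = total frames / recording length (s)
    total dropped       = target FPS x recording length (s) - 1 - total frames
    dropped per minute  = total dropped / recording length (s) x 60
    apparent playback   = total frames / target FPS

The "- 1" in the total-dropped equation is a fence-post convention and is
kept literal, so a complete stream can report total_dropped of 0 (or even
-1 for a stream one frame over target) and the value may be fractional.
The exact values are reported; 2-decimal roundings (half away from zero,
matching the precision such results are printed at) are separate fields.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

from .io import RecordingMeta, TimestampTable, recording_length


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DroppedFrameReport:
    total_frames: int
    recording_length_s: float
    target_fps: float
    true_fps: float
    true_fps_2dp: float
    total_dropped: float
    dropped_per_min: float
    dropped_per_min_2dp: float
    apparent_playback_s: float
    negative_dropped_warning: bool

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_dropped(table: TimestampTable, meta: RecordingMeta) -> DroppedFrameReport:
    """Apply the dropped-frame equations to a timestamp table.

    Recording length is the last frame's onset.  A negative total_dropped
    (more frames than the target rate predicts) is reported as-is with a
    warning flag rather than clipped.
    """
    length = recording_length(table)
    if not length > 0:
        raise ValueError("recording length must be positive")
    total = len(table)
    true_fps = total / length
    total_dropped = meta.target_fps * length - 1 - total
    dropped_per_min = total_dropped / length * 60.0
    return DroppedFrameReport(
        total_frames=total,
        recording_length_s=length,
        target_fps=meta.target_fps,
        true_fps=true_fps,
        true_fps_2dp=round_half_away(true_fps),
        total_dropped=total_dropped,
        dropped_per_min=dropped_per_min,
        dropped_per_min_2dp=round_half_away(dropped_per_min),
        apparent_playback_s=total / meta.target_fps,
        negative_dropped_warning=total_dropped < 0,
    )
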