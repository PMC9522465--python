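"""Centroid tracking and locomotor activity measures.

A deliberately simple tracker sufficient for quantifying how radial image
distortion biases locomotor measures: per frame, threshold the grayscale
image by polarity, keep the largest connected component above a minimum
area, and take its intensity-weighted centroid.  From the resulting
trajectory the standard open-field measures follow: total distance
travelled, average speed, and time spent on either side of the apparatus,
plus per-zone distance and speed.

Frames with no qualifying component are MISSING (NaN); steps across a gap
are skipped, not interpolated — conservative for distance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .duplicates import grayscale
from .io import FrameStream


class InsufficientTrackError(ValueError):
    """Fewer than two usable (non-MISSING) trajectory samples."""


@dataclass
class Trajectory:
    """Per-frame (x, y) pixel positions; NaN rows mark MISSING samples."""

    samples: np.ndarray  # (F, 2) float, NaN = MISSING
    fps: float
    px_per_cm: float
    all_missing_warning: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 2)
        if not self.px_per_cm > 0:
            raise ValueError("px_per_cm must be positive")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.samples).any(axis=1)


@dataclass(frozen=True)
class ZoneSpec:
    """Vertical split of the arena at pixel x = boundary.

    Samples with x <= boundary belong to the left label (boundary ties go
    left).
    """

    boundary: float
    labels: tuple[str, str] = ("left", "right")


@dataclass(frozen=True)
class LocomotorReport:
    total_distance_cm: float
    average_speed_cm_s: float
    tracked_duration_s: float
    time_per_zone_s: dict[str, float]
    distance_per_zone_cm: dict[str, float]
    speed_per_zone_cm_s: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def track_centroid(
    stream: FrameStream,
    polarity: str = "dark_on_light",
    intensity_threshold: int = 120,
    min_area_px: int = 20,
    px_per_cm: float = 10.0,
) -> Trajectory:
    """Track the animal as the largest thresholded blob's weighted centroid.

    ``dark_on_light`` keeps pixels <= threshold (dark animal, light floor);
    ``light_on_dark`` keeps pixels >= threshold.  The centroid is weighted
    by contrast against the background so the estimate is subpixel.
    """
    if polarity not in ("dark_on_light", "light_on_dark"):
        raise ValueError("polarity must be 'dark_on_light' or 'light_on_dark'")
    out = np.full((len(stream), 2), np.nan)
    for i, frame in enumerate(stream.frames):
        g = grayscale(frame)
        if polarity == "dark_on_light":
            fg = g <= intensity_threshold
            weights = 255.0 - g
        else:
            fg = g >= intensity_threshold
            weights = g.astype(float)
        labels, n = ndimage.label(fg)
        if n == 0:
            continue
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        best = int(np.argmax(areas)) + 1
        if areas[best - 1] < min_area_px:
            continue
        w = np.where(labels == best, weights, 0.0)
        cy, cx = ndimage.center_of_mass(w)
        out[i] = (cx, cy)
    return Trajectory(
        out,
        fps=stream.nominal_fps,
        px_per_cm=px_per_cm,
        all_missing_warning=bool(np.isnan(out).all()),
    )


def locomotor_measures(traj: Trajectory, zones: ZoneSpec) -> LocomotorReport:
    """Distance, speed, and zone-occupancy measures from a trajectory.

    Distance sums Euclidean steps between consecutive non-MISSING frames
    only (gap-spanning steps are excluded).  Tracked duration is the number
    of non-MISSING samples over the frame rate; zone times partition it.
    Each step is assigned to the zone of its starting sample.
    """
    valid = traj.valid
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise InsufficientTrackError(
            f"need >= 2 non-missing samples, got {n_valid}"
        )
    xy = traj.samples
    left, right = zones.labels
    in_left = xy[:, 0] <= zones.boundary

    both = valid[:-1] & valid[1:]
    steps_px = np.hypot(*(xy[1:] - xy[:-1]).T)
    steps_cm = np.where(both, steps_px, 0.0) / traj.px_per_cm

    total_cm = float(steps_cm.sum())
    duration_s = n_valid / traj.fps
    start_left = in_left[:-1]
    dist_zone = {
        left: float(steps_cm[start_left & both].sum()),
        right: float(steps_cm[~start_left & both].sum()),
    }
    time_zone = {
        left: float((valid & in_left).sum() / traj.fps),
        right: float((valid & ~in_left).sum() / traj.fps),
    }
    speed_zone = {
        lab: (dist_zone[lab] / time_zone[lab] if time_zone[lab] > 0 else 0.0)
        for lab in (left, right)
    }
    return LocomotorReport(
        total_distance_cm=total_cm,
        average_speed_cm_s=total_cm / duration_s,
        tracked_duration_s=duration_s,
        time_per_zone_s=time_zone,
        distance_per_zone_cm=dist_zone,
        speed_per_zone_cm_s=speed_zone,
    )
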