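"""Ground-truthed synthetic recording sessions.

Everything the analysis modules consume can be generated here with known
defects: timestamp tables with controlled frame drops, rendered moving-
blob videos with injected exact-copy duplicate frames, per-lighting sensor
noise, and optional radial distortion of a known trajectory.  Each
generator returns the artifact plus a :class:`GroundTruthManifest` whose
expected summary values are recomputable from the injected defect lists
via the same accounting equations the analyses implement.

Duplicates *replace* frames with a copy of their predecessor rather than
inserting, so nominal timing is preserved — the scenario where a camera
"achieves" its frame rate while delivering lower temporal resolution.
All randomness is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .fisheye import DistortionParams, warp_image
from .io import FrameStream, TimestampTable, UNBOUNDED

#: Invented per-lighting sensor-noise calibrations (grayscale std dev units).
LIGHTING_NOISE_SIGMA = {
    "no_light": 1.0,
    "cue": 1.0,
    "red": 1.5,
    "white": 2.5,
    "white_cue": 2.5,
}


# --- trajectory primitives -------------------------------------------------

@dataclass(frozen=True)
class Stationary:
    pass


@dataclass(frozen=True)
class Circle:
    radius_px: float
    period_s: float


@dataclass(frozen=True)
class Square:
    side_px: float
    period_s: float


@dataclass(frozen=True)
class RandomWalk:
    step_sigma_px: float


def _trajectory_positions(kind, n_frames, fps, center, bounds, rng):
    cx, cy = center
    t = np.arange(n_frames) / fps
    if isinstance(kind, Stationary):
        return np.column_stack([np.full(n_frames, cx), np.full(n_frames, cy)])
    if isinstance(kind, Circle):
        ang = 2 * math.pi * t / kind.period_s
        return np.column_stack([cx + kind.radius_px * np.cos(ang),
                                cy + kind.radius_px * np.sin(ang)])
    if isinstance(kind, Square):
        # constant-speed traversal of an axis-aligned square centered on (cx, cy)
        half = kind.side_px / 2.0
        s = (t / kind.period_s) % 1.0 * 4.0  # position along perimeter in sides
        leg = np.floor(s).astype(int)
        frac = s - leg
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        corners = np.array([(-half, -half), (half, -half), (half, half),
                            (-half, half), (-half, -half)])
        for k in range(4):
            m = leg == k
            x[m] = corners[k, 0] + (corners[k + 1, 0] - corners[k, 0]) * frac[m]
            y[m] = corners[k, 1] + (corners[k + 1, 1] - corners[k, 1]) * frac[m]
        return np.column_stack([cx + x, cy + y])
    if isinstance(kind, RandomWalk):
        steps = rng.normal(0.0, kind.step_sigma_px, size=(n_frames, 2))
        steps[0] = 0.0
        pos = np.cumsum(steps, axis=0) + (cx, cy)
        # reflect at the allowed bounding box so the blob stays in frame
        (x0, x1), (y0, y1) = bounds
        for dim, (lo, hi) in enumerate(((x0, x1), (y0, y1))):
            span = hi - lo
            folded = np.mod(pos[:, dim] - lo, 2 * span)
            pos[:, dim] = lo + np.where(folded > span, 2 * span - folded, folded)
        return pos
    raise TypeError(f"unknown trajectory spec {kind!r}")


@dataclass
class SessionSpec:
    """Complete description of a synthetic recording session.

    Defaults emulate the benchmark recording regime of the duplicate-frame
    comparison: 300 s at a nominal 30 FPS.  Frames are rendered grayscale
    at a reduced 160x120 resolution — per-frame accounting depends only on
    counts and durations, never on pixel count.
    """

    duration_s: float = 300.0
    nominal_fps: float = 30.0
    resolution: tuple[int, int] = (160, 120)  # (width, height)
    trajectory: object = field(default_factory=lambda: Circle(40.0, 5.0))
    blob_radius_px: float = 8.0
    polarity: str = "dark_on_light"
    background_intensity: int = 200
    blob_intensity: int = 40
    lighting: str = "white"
    noise_sigma: float | None = None  # None -> LIGHTING_NOISE_SIGMA[lighting]
    n_duplicates: int = 0
    duplicate_positions: tuple[int, ...] | None = None  # explicit, else seeded
    renoise_duplicates: bool = False
    distortion_power: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.duration_s > 0 or not self.nominal_fps > 0:
            raise ValueError("duration_s and nominal_fps must be positive")
        if self.polarity == "light_on_dark":
            # swap default intensities for IR-style footage
            if self.background_intensity > self.blob_intensity:
                self.background_intensity, self.blob_intensity = (
                    self.blob_intensity, self.background_intensity)

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * self.nominal_fps)

    @property
    def sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        return LIGHTING_NOISE_SIGMA[self.lighting]


@dataclass
class GroundTruthManifest:
    """Injected defects + true trajectory, with expected summary values."""

    seed: int
    n_frames: int
    duration_s: float
    nominal_fps: float
    duplicate_positions: tuple[int, ...] = ()
    kept_onsets: np.ndarray | None = field(default=None, repr=False)
    trajectory_px: np.ndarray | None = field(default=None, repr=False)
    distortion_power: float = 0.0
    expected: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kept_onsets"] = None if self.kept_onsets is None else list(self.kept_onsets)
        d["trajectory_px"] = (
            None if self.trajectory_px is None else self.trajectory_px.tolist()
        )
        d["duplicate_positions"] = list(self.duplicate_positions)
        return d


# --- timestamp fixtures ----------------------------------------------------

def make_timestamp_fixture(
    n_frames: int,
    length_s: float,
    target_fps: float,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TimestampTable, GroundTruthManifest]:
    """Uniform (optionally jittered) onset table spanning [0, length_s].

    Onsets are uniform from 0 to length_s inclusive; interior onsets may be
    Gaussian-jittered (re-sorted, endpoints pinned, re-drawn on collision).
    Offsets equal the next onset; the final offset is the UNBOUNDED
    sentinel.  The manifest carries the dropped-frame summaries expected
    from the accounting equations.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not length_s > 0:
        raise ValueError("length_s must be positive")
    onsets = np.linspace(0.0, length_s, n_frames)
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        for _ in range(100):
            trial = onsets.copy()
            trial[1:-1] += rng.normal(0.0, jitter_sigma, n_frames - 2)
            trial = np.sort(trial)
            if np.all(np.diff(trial) > 0) and trial[0] >= 0:
                onsets = trial
                break
        else:
            raise RuntimeError("could not draw strictly increasing jittered onsets")
        onsets[0], onsets[-1] = 0.0, length_s
    offsets = np.append(onsets[1:], UNBOUNDED)
    table = TimestampTable.from_arrays(onsets, offsets)

    total_dropped = target_fps * length_s - 1 - n_frames
    manifest = GroundTruthManifest(
        seed=seed,
        n_frames=n_frames,
        duration_s=length_s,
        nominal_fps=target_fps,
        kept_onsets=onsets,
        expected={
            "true_fps": n_frames / length_s,
            "total_dropped": total_dropped,
            "dropped_per_min": total_dropped / length_s * 60.0,
            "apparent_playback_s": n_frames / target_fps,
        },
    )
    return table, manifest


# --- rendered video sessions ----------------------------------------------

def _render_blob_frames(spec: SessionSpec, positions: np.ndarray) -> np.ndarray:
    w, h = spec.resolution
    r = spec.blob_radius_px
    margin = r + 1
    bad = np.flatnonzero(
        (positions[:, 0] < margin) | (positions[:, 0] > w - 1 - margin)
        | (positions[:, 1] < margin) | (positions[:, 1] > h - 1 - margin)
    )
    if bad.size:
        raise ValueError(
            f"blob leaves the frame at frame {int(bad[0])} "
            f"(center {tuple(positions[bad[0]])}, radius {r}, frame {w}x{h})"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((len(positions), h, w), dtype=np.uint8)
    for i, (cx, cy) in enumerate(positions):
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        f = np.full((h, w), spec.background_intensity, dtype=np.uint8)
        f[mask] = spec.blob_intensity
        frames[i] = f
    return frames


def inject_duplicates(stream: FrameStream, positions) -> FrameStream:
    """Replace the frame at each position with a bit-copy of its predecessor.

    Positions are applied in increasing order, so a run of consecutive
    positions freezes the stream on the frame preceding the run.  Frame
    count is unchanged.
    """
    positions = sorted(int(p) for p in positions)
    n = len(stream)
    if positions and (positions[0] < 1 or positions[-1] > n - 1):
        raise IndexError(f"duplicate positions must lie in [1, {n - 1}]")
    frames = stream.frames.copy()
    for p in positions:
        frames[p] = frames[p - 1]
    return FrameStream(frames, nominal_fps=stream.nominal_fps)


def render_session(spec: SessionSpec) -> tuple[FrameStream, GroundTruthManifest]:
    """Render a session per spec: blob + noise + distortion + duplicates.

    Rendering order: draw the blob along the trajectory, add seeded
    Gaussian sensor noise (clipped to [0, 255]), apply radial distortion if
    requested, then inject duplicate frames.  Injected duplicates are
    bit-identical copies by default; with ``renoise_duplicates`` each
    duplicated frame re-draws its own sensor noise over the frozen scene
    (emulating a motionless re-capture rather than a buffer copy).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    w, h = spec.resolution
    margin = spec.blob_radius_px + 2
    bounds = ((margin, w - 1 - margin), (margin, h - 1 - margin))
    positions = _trajectory_positions(
        spec.trajectory, n, spec.nominal_fps, (w / 2.0, h / 2.0), bounds, rng
    )
    clean = _render_blob_frames(spec, positions)

    if spec.distortion_power != 0.0:
        params = DistortionParams(spec.distortion_power)
        clean = np.stack([warp_image(f, params, "distort") for f in clean])

    if spec.duplicate_positions is not None:
        dup_positions = tuple(sorted(int(p) for p in spec.duplicate_positions))
    elif spec.n_duplicates:
        dup_positions = tuple(sorted(
            int(p) for p in
            rng.choice(np.arange(1, n), size=spec.n_duplicates, replace=False)
        ))
    else:
        dup_positions = ()
    if dup_positions and (dup_positions[0] < 1 or dup_positions[-1] > n - 1):
        raise IndexError(f"duplicate positions must lie in [1, {n - 1}]")

    # content_idx[i] = index of the clean frame shown at slot i after the
    # freeze-on-predecessor duplication semantics
    content_idx = np.arange(n)
    for p in dup_positions:
        content_idx[p] = content_idx[p - 1]

    sigma = spec.sigma
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=clean.shape)
        noisy = np.clip(np.rint(clean.astype(np.float64) + noise), 0, 255).astype(np.uint8)
    else:
        noisy = clean

    if spec.renoise_duplicates and sigma > 0:
        base = clean[content_idx].astype(np.float64)
        fresh = rng.normal(0.0, sigma, size=base.shape)
        frames = np.clip(np.rint(base + fresh), 0, 255).astype(np.uint8)
    else:
        frames = noisy[content_idx]

    stream = FrameStream(frames, nominal_fps=spec.nominal_fps)
    d = len(dup_positions)
    manifest = GroundTruthManifest(
        seed=spec.seed,
        n_frames=n,
        duration_s=spec.duration_s,
        nominal_fps=spec.nominal_fps,
        duplicate_positions=dup_positions,
        trajectory_px=positions,
        distortion_power=spec.distortion_power,
        expected={
            "total_duplicates": d,
            "duplicates_per_min": d / spec.duration_s * 60.0,
            "true_fps_container": (n - d) / (n / spec.nominal_fps),
        },
    )
    return stream, manifest
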