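"""One-parameter radial fisheye distortion family.

The radial map, in image-normalized coordinates (radius r measured from
the image center and divided by the half-diagonal so the corners sit at
r = 1), is the odd polynomial

    r' = r * (1 + power * (1 - r^2))

which honors the usual sign contract of single-knob fisheye shaders: a
positive power bulges the image outward (adds barrel/fisheye distortion),
a negative power pulls it inward (corrects distortion), and zero is the
identity.  r = 0 and r = 1 are fixed points, and for |power| < 0.5 the map
is strictly increasing on [0, 1] (derivative 1 + power*(1 - 3 r^2) > 0),
so it is invertible.  The inverse has no closed form and is solved by
bisection.

This family is the package's own; it is *not* claimed to be pixel-
equivalent to any particular third-party shader implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


class InvalidPowerError(ValueError):
    """|power| >= 0.5 would make the radial map non-monotone on [0, 1]."""


@dataclass(frozen=True)
class DistortionParams:
    """Radial distortion: signed strength, center, and normalization radius.

    ``center`` is in normalized image coordinates (fractions of width and
    height, default the image midpoint); ``norm_radius`` is the half
    image diagonal in pixels, making ``power`` resolution-independent.
    """

    power: float
    center: tuple[float, float] = (0.5, 0.5)
    norm_radius: float | None = None  # derived from image size when None

    def __post_init__(self):
        if not abs(self.power) < 0.5:
            raise InvalidPowerError(
                f"|power| must be < 0.5 for a monotone radial map, got {self.power}"
            )
        if self.norm_radius is not None and not self.norm_radius > 0:
            raise ValueError("norm_radius must be positive")

    def resolved(self, width: int, height: int) -> "DistortionParams":
        """Fill in norm_radius (half diagonal) and pixel center for an image."""
        if self.norm_radius is not None:
            return self
        return DistortionParams(
            self.power, self.center, float(np.hypot(width, height)) / 2.0
        )

    def center_px(self, width: int, height: int) -> tuple[float, float]:
        return (self.center[0] * width, self.center[1] * height)


def _radial_forward(r: np.ndarray, power: float) -> np.ndarray:
    return r * (1.0 + power * (1.0 - r * r))


def _radial_inverse(r_prime: np.ndarray, power: float, tol: float = 1e-10) -> np.ndarray:
    """Invert the radial map by bisection on [0, 1.5]."""
    r_prime = np.asarray(r_prime, dtype=np.float64)
    lo = np.zeros_like(r_prime)
    # for positive power the forward map peaks at sqrt((1+p)/(3p)); keep the
    # bracket inside the increasing branch so bisection stays well-posed
    hi_val = 1.5 if power <= 0 else min(1.5, float(np.sqrt((1 + power) / (3 * power))))
    hi = np.full_like(r_prime, hi_val)
    if np.any(_radial_forward(hi, power) < r_prime):
        raise RuntimeError("radial inverse: target outside bracketing interval")
    # ~60 halvings of 1.5 reach well below 1e-10
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        below = _radial_forward(mid, power) < r_prime
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    r = 0.5 * (lo + hi)
    if np.any(np.abs(_radial_forward(r, power) - r_prime) > max(tol, 1e-10) * 10):
        raise RuntimeError("radial inverse failed to converge")
    return r


def _map_points(points: np.ndarray, params: DistortionParams,
                width: int, height: int, inverse: bool) -> np.ndarray:
    p = params.resolved(width, height)
    if p.power == 0.0:
        return np.asarray(points, dtype=np.float64).copy()
    cx, cy = p.center_px(width, height)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    r = np.hypot(dx, dy) / p.norm_radius
    with np.errstate(invalid="ignore", divide="ignore"):
        r_new = _radial_inverse(r, p.power) if inverse else _radial_forward(r, p.power)
        scale = np.where(r > 0, r_new / np.where(r > 0, r, 1.0), 1.0)
    out = np.column_stack([cx + dx * scale, cy + dy * scale])
    return out.reshape(np.asarray(points, dtype=np.float64).shape)


def distort_point(point, params: DistortionParams, width: int, height: int):
    """Forward radial map of pixel coordinates (x, y); direction preserved."""
    return _map_points(point, params, width, height, inverse=False)


def undistort_point(point, params: DistortionParams, width: int, height: int):
    """Exact numerical inverse of :func:`distort_point` (bisection)."""
    return _map_points(point, params, width, height, inverse=True)


def warp_image(frame: np.ndarray, params: DistortionParams,
               direction: str = "correct") -> np.ndarray:
    """Resample a frame under the radial map by inverse mapping.

    ``direction="distort"`` produces the fisheye-distorted image;
    ``"correct"`` produces the corrected image.  Bilinear interpolation;
    samples falling outside the source are filled black.
    """
    if direction not in ("distort", "correct"):
        raise ValueError("direction must be 'distort' or 'correct'")
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    p = params.resolved(w, h)
    if p.power == 0.0:
        return frame.copy()
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    # inverse mapping: for each output pixel, sample the source at its preimage
    inverse = direction == "distort"
    src = _map_points(targets, p, w, h, inverse=inverse)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])

    def _resample(channel):
        return map_coordinates(channel.astype(np.float64), coords, order=1,
                               mode="constant", cval=0.0)

    if frame.ndim == 2:
        out = _resample(frame)
    else:
        out = np.stack([_resample(frame[:, :, c]) for c in range(frame.shape[2])],
                       axis=-1)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def warp_stream(stream, params: DistortionParams, direction: str = "correct"):
    """Apply :func:`warp_image` to every frame of a stream."""
    from .io import FrameStream

    warped = np.stack([warp_image(f, params, direction) for f in stream.frames])
    return FrameStream(warped, nominal_fps=stream.nominal_fps)
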