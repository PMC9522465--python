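# Methods

`vidqc` quantifies frame-integrity defects in behavioral video recordings
and the effect of radial lens distortion on locomotor measures. This note
documents the models and procedures, the parameters that matter, what the
synthetic-session generator does and does not emulate, and the numerical
choices made where the design was open.

## Frame accounting

Acquisition systems in behavioral neuroscience exhibit two distinct
failure modes relative to the acquisition set point (the *target FPS*):

* **Dropped frames** — frame slots never delivered. The file holds fewer
  frames than the target rate predicts, so third-party players that
  assume the nominal rate play it fast-forwarded and shortened.
* **Duplicate frames** — the nominal rate is met, but some frames are
  repeats of their predecessor, so effective temporal resolution is lower
  ("choppy" playback).

### Recording length

Two conventions coexist, and both are exposed and labelled:

* **Timestamped streams** (`recording_length`): the onset timestamp of
  the very last frame. Acquisition platforms that store per-frame
  onset/offset pairs leave the final offset as an unbounded sentinel
  (serialized as the literal token `inf`), so the last onset is the only
  well-defined endpoint.
* **Container videos** (`container_length`): `frame_count / nominal_fps`,
  the only length derivable from a plain video file.

### Dropped-frame equations

With `L` the recording length in seconds, `N` the total frame count and
`f_t` the target FPS:

    true FPS              = N / L
    total dropped frames  = f_t * L - 1 - N
    dropped frames / min  = total dropped / L * 60
    apparent playback (s) = N / f_t

The `- 1` is a fence-post convention and is kept literal: a complete
stream can legitimately report `total_dropped` of 0 or even −1, and the
value may be fractional. Values are reported exactly; separate `*_2dp`
fields round to 2 decimals with ties away from zero, the precision such
benchmarks are printed at. A useful identity that follows algebraically
and is enforced in the tests:

    dropped/min = (f_t - true FPS) * 60 - 60 / L

### Duplicate-frame detection

Color frames are converted to grayscale with fixed Rec.601 luma weights
(0.299 R + 0.587 G + 0.114 B, rounded to nearest), documented so results
are reproducible bit for bit. For each consecutive frame pair the
statistic is the **maximum over pixels of the absolute grayscale
difference**, computed in a widened integer type so 8-bit wraparound
cannot occur. Pairs with statistic ≤ threshold are duplicates (boundary
inclusive; the later frame of the pair is the duplicate). The
duplicate-adjusted rate and per-minute count are

    true FPS              = (N - duplicates) / L
    duplicate frames/min  = duplicates / L * 60

Field presets for the threshold are 8 under red house-light illumination
and 10 under white (configurable).

**Automatic threshold selection.** On duplicate-ridden footage the
change-statistic histogram is bimodal: a low mode from duplicates and a
high mode from motion. The selector builds the integer histogram over
0–255, smooths it with a centered moving average (window 5, default), and
finds the two tallest local maxima at least 5 intensity units apart. If
the valley between them dips to ≤ 50% of the lower peak, the valley
location is the threshold; otherwise the distribution is declared
unimodal and *no* threshold is returned — duplicate quantities come back
undefined with an explicit `unimodal_flag`, never a silent zero. The
smoothing window and saddle-depth fraction are simple deterministic
choices, exposed as parameters; they reproduce the qualitative
bimodal/unimodal split on the synthetic regimes below.

**Confound.** A max-change statistic cannot distinguish a duplicated
frame from an animal that genuinely did not move. Reports therefore carry
two pieces of caveat metadata: the bimodality flag, and a temporal
**evenness** diagnostic — the variance-to-mean ratio of per-bin duplicate
counts (bin width 60 s, matching the per-minute reporting unit).
Hardware duplication arrives evenly through a recording (VMR near 0);
genuine stillness clusters (large VMR).

## Fisheye distortion model

A one-parameter radial family in normalized coordinates (radius measured
from the image center, divided by the half-diagonal so power is
resolution-independent and the corners sit at r = 1):

    r' = r * (1 + power * (1 - r^2))

Positive power adds barrel/fisheye distortion, negative power corrects
it, zero is the identity; r = 0 and r = 1 are fixed points. For
|power| < 0.5 the derivative 1 + power·(1 − 3r²) is positive on [0, 1],
so the map is strictly monotone and invertible; |power| ≥ 0.5 is
rejected. The inverse has no closed form and is solved by bisection
(64 halvings, residual well under 1e-10), giving point round trips below
1e-8 px. Image warps use inverse mapping with bilinear interpolation;
samples outside the source are filled black. The shader-based tools this
emulates do not publish their transfer function, so pixel equivalence
with any particular plugin is explicitly **not** claimed — only the sign
contract and fixed boundary.

## Locomotor tracking

A deliberately minimal stand-in for commercial tracking software,
sufficient for *relative* comparisons across distortion conditions: per
frame, threshold the grayscale image by polarity (`dark_on_light` keeps
pixels ≤ threshold; `light_on_dark` ≥), keep the largest connected
component with area ≥ `min_area_px`, and take its contrast-weighted
centroid (subpixel). Frames with no qualifying component are MISSING.

Measures: total distance is the sum of Euclidean steps between
consecutive non-MISSING frames divided by `px_per_cm`; steps spanning a
MISSING gap are skipped, not interpolated — conservative for distance.
Tracked duration is (non-MISSING samples)/fps; zone times partition it
under a vertical split of the arena (boundary ties go to the left
label); each step is assigned to the zone of its starting sample, so
per-zone distances sum to the total.

Note that the correction warp fills regions outside the source image
with black; when tracking corrected footage of a dark animal on a light
floor, restrict the arena or use `light_on_dark` material so the fill
region cannot be picked up as the largest dark component.

## Synthetic sessions

The generator renders a moving disk (default radius 8 px, intensity 40 on
a 200 background; polarity switchable for IR-style footage) along a
stationary, circular, square or random-walk trajectory, adds seeded
Gaussian sensor noise, optionally applies the radial distortion above,
and then injects duplicate frames. Duplicates **replace** frames with a
copy of their predecessor (runs of positions freeze the scene), so
nominal timing is preserved — the scenario where a camera "achieves" its
frame rate while delivering less temporal information. Timestamp fixtures
place onsets uniformly (optionally jittered) across the recording with
the final offset unbounded. Every artifact ships with a ground-truth
manifest whose expected summaries are recomputed from the injected-defect
lists via the same equations the analyses implement, closing the loop in
the end-to-end tests.

Defaults define the emulated benchmark conditions: 300 s sessions at a
nominal 30 FPS (duplicate analysis) and 20 FPS target for timestamp
fixtures (dropped analysis); circle radius 40 px with a 5 s period so
every per-frame motion step moves the disk edge by more than a pixel
(max-change ≈ 160, far above any duplicate threshold); per-lighting noise
sigmas are invented calibration knobs (red 1.5, white 2.5 grayscale
units). Frames render grayscale at 160×120: per-frame accounting depends
only on counts and durations, never pixel count, and this keeps a 9,000
frame session cheap to render and analyze.

Noise ordering: sensor noise is drawn after distortion (noise arises at
the sensor, downstream of the optics) and duplicates are injected last as
bit-copies, noise included. The optional `renoise_duplicates` flag
instead re-draws noise on each duplicated frame over the frozen scene,
emulating a motionless re-capture; with sigma 0.5 this produces the
bimodal low mode (duplicate-pair max change ≤ ~4) used by the
threshold-selection regime tests, while a stationary-blob session with
the same noise produces the unimodal case.

What the generator does **not** emulate: photorealistic animals, lighting
flare/reflections, codec compression artifacts (the built-in writer is
lossless uncompressed AVI), or rolling-shutter effects. Passing tests
demonstrate the accounting, classification and geometry are correct on
controlled inputs; they do not certify threshold presets for any
particular real camera or lighting rig.

## Numerical and I/O choices

* Video I/O is a built-in uncompressed RIFF/AVI codec (8-bit grayscale
  with palette, or 24-bit BGR DIB frames): lossless by construction, so
  injected duplicates remain bit-identical after a write/read round trip.
  Other containers are accepted only if an ffmpeg-capable imageio plugin
  is installed.
* Timestamp CSVs are read with round-trip float parsing so write→read is
  value-identical, including the `inf` sentinel.
* Times are double-precision seconds; frame indices and coordinates are
  0-based; printed-precision rounding is half away from zero, kept in
  separate report fields so exact values remain available.
* Degenerate inputs raise typed errors (fewer than 2 timestamp rows,
  fewer than 2 frames, empty streams, out-of-range thresholds or
  duplicate positions) rather than returning defaults; a negative
  total-dropped count is returned as-is with a warning flag.

## Problem sizes

The test suite renders 20 s sessions (600 frames at 160×120) for module
tests and full 300 s / 9,000-frame sessions for the benchmark
reconstructions; the whole suite runs in well under a minute on one CPU.
`scripts/acceptance.py` reconstructs the benchmark values from 2,489 /
3,471 / 5,999-row timestamp tables and two 9,000-frame rendered sessions
in a few seconds.
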