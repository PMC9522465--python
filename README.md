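# vidqc

Frame-integrity quality control for behavioral-neuroscience video
recordings.

Affordable USB cameras and DIY acquisition rigs are now standard in
rodent behavioral labs, but the video they deliver is not always the
video that was requested: acquisition pipelines silently **drop** frames
(playback appears fast-forwarded and shortened) or deliver **duplicate**
frames (the nominal rate is met but temporal resolution is lower), and
wide-angle fisheye lenses radially distort the image enough to bias
position-tracking measures. All three defects quietly corrupt the
alignment of behavior with neural recordings and the locomotor statistics
derived from tracking. `vidqc` is for experimenters who want to audit
their recordings — or their cameras — before trusting them.

## What it computes

**Dropped frames**, from a per-frame timestamp table (CSV of
`frame_index,onset_s,offset_s`, final offset may be `inf`) and the target
rate `f_t`, with recording length `L` = last-frame onset and `N` total
frames:

    true FPS = N / L        total dropped = f_t · L − 1 − N
    dropped/min = total dropped / L · 60        playback length = N / f_t

**Duplicate frames**, from the video itself: frames are grayscaled
(Rec.601), the max absolute pixel change is computed per consecutive
pair, and pairs at or below a threshold are duplicates. The threshold is
either a lighting preset (8 red / 10 white house light) or found
automatically at the valley of the bimodal change histogram; unimodal
distributions (e.g. a motionless animal) are flagged instead of silently
scored. The duplicate-adjusted rate is `(N − duplicates) / L`, and a
variance-to-mean evenness diagnostic separates even hardware duplication
from clustered stillness.

**Fisheye distortion**, as the one-parameter radial map
`r' = r(1 + power(1 − r²))` on half-diagonal-normalized radius: positive
power adds distortion, negative corrects, zero is the identity; the
inverse is solved numerically to sub-1e-8 px round trips.

**Locomotor measures** — total distance, average speed, per-side time and
distance — from a minimal largest-blob centroid tracker, sufficient to
quantify how distortion and its correction change tracked distance.

**Synthetic sessions**: every analysis is testable without real footage
via a seeded generator that renders moving-blob videos with injected
exact-copy duplicates, timestamp tables with controlled drops,
per-lighting noise regimes and optional distortion, plus a ground-truth
manifest of every injected defect.

## Worked example

Reconstruct a red-house-light benchmark recording — 2,489 delivered
frames over a 300 s session at a 20 FPS set point — and account for the
missing frames:

```python
import vidqc

table, _ = vidqc.make_timestamp_fixture(n_frames=2489, length_s=300.0, target_fps=20.0)
report = vidqc.analyze_dropped(table, vidqc.RecordingMeta(target_fps=20, lighting="red"))
print(report.to_dict())
```

```
{"total_frames": 2489, "recording_length_s": 300.0, "target_fps": 20,
 "true_fps": 8.296666666666667, "true_fps_2dp": 8.3,
 "total_dropped": 3510.0, "dropped_per_min": 702.0, "dropped_per_min_2dp": 702.0,
 "apparent_playback_s": 124.45, "negative_dropped_warning": false}
```

The camera achieved 8.30 FPS instead of 20: it dropped 702 frames per
minute, and a media player assuming 20 FPS would show the 300 s session
in 124.45 s. Duplicates are the complementary failure — render a 300 s,
9,000-frame session with 6,517 injected exact-copy duplicates and detect
them at the red-light threshold:

```python
spec = vidqc.SessionSpec(duration_s=300.0, noise_sigma=0.0, n_duplicates=6517, seed=42)
stream, manifest = vidqc.render_session(spec)
dup = vidqc.analyze_duplicates(stream, vidqc.RecordingMeta(30, "red"), 8)
print(dup.total_duplicates, dup.duplicates_per_min_2dp, dup.true_fps_2dp)
# 6517 1303.4 8.28
```

All 6,517 injected duplicates are recovered: 1303.40 duplicates/min, so
despite a nominal 30 FPS the video carries only 8.28 new frames per
second. The same operations are available from the shell:

```
vidqc drops --timestamps ts.csv --target-fps 20
vidqc dupes session.avi --threshold 8 --target-fps 30
vidqc fisheye in.avi out.avi --power 0.3 --direction correct
vidqc track session.avi --px-per-cm 10 --zone-split 80
vidqc simulate --spec spec.json --out-video v.avi --out-manifest m.json
```

See `docs/methods.md` for the models, parameter defaults and numerical
conventions.

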