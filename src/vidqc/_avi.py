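"""Minimal uncompressed RIFF/AVI codec.

Writes and reads AVI files whose video stream is raw device-independent
bitmaps ('DIB ' handler, BI_RGB): 8-bit with a grayscale palette or 24-bit
BGR, rows bottom-up and padded to 4-byte boundaries.  Raw DIB is lossless,
so bit-identical duplicate frames survive a write/read round trip — the
property the duplicate-frame analysis depends on.  Only this profile is
produced; the reader accepts any AVI in the same profile.
"""

from __future__ import annotations

import struct

import numpy as np

_AVIF_HASINDEX = 0x00000010
_FPS_TIMEBASE = 1_000_000  # rate/scale denominator for fractional frame rates


def _pad_rows(frame_2d: np.ndarray, bytes_per_px: int) -> bytes:
    h, w = frame_2d.shape[:2]
    row_bytes = w * bytes_per_px
    stride = (row_bytes + 3) & ~3
    buf = np.zeros((h, stride), dtype=np.uint8)
    flat = frame_2d[::-1].reshape(h, row_bytes)  # bottom-up row order
    buf[:, :row_bytes] = flat
    return buf.tobytes()


def _encode_frame(frame: np.ndarray) -> bytes:
    if frame.ndim == 2:
        return _pad_rows(frame, 1)
    # RGB in memory -> BGR on disk
    return _pad_rows(frame[:, :, ::-1], 3)


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write a (F, H, W) or (F, H, W, 3) uint8 array as an uncompressed AVI."""
    frames = np.asarray(frames, dtype=np.uint8)
    if frames.ndim not in (3, 4):
        raise ValueError("frames must be (F, H, W) or (F, H, W, 3)")
    n, h, w = frames.shape[:3]
    color = frames.ndim == 4
    bits = 24 if color else 8
    row_bytes = w * (3 if color else 1)
    stride = (row_bytes + 3) & ~3
    frame_size = stride * h
    rate = round(fps * _FPS_TIMEBASE)

    avih = struct.pack(
        "<14I",
        round(1e6 / fps),  # dwMicroSecPerFrame
        frame_size * max(1, round(fps)),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        _AVIF_HASINDEX,
        n, 0, 1,  # dwTotalFrames, dwInitialFrames, dwStreams
        frame_size,  # dwSuggestedBufferSize
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIiI4H",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        _FPS_TIMEBASE, rate,  # dwScale, dwRate: fps = rate / scale
        0, n, frame_size, -1, 0,
        0, 0, w, h,
    )
    strf = struct.pack(
        "<IiiHHIIiiII",
        40, w, h, 1, bits, 0,  # BI_RGB
        frame_size, 0, 0, 256 if bits == 8 else 0, 0,
    )
    if bits == 8:
        # grayscale palette: entry i = (B=i, G=i, R=i, reserved)
        pal = np.zeros((256, 4), dtype=np.uint8)
        pal[:, :3] = np.arange(256, dtype=np.uint8)[:, None]
        strf += pal.tobytes()

    def chunk(fcc: bytes, payload: bytes) -> bytes:
        data = fcc + struct.pack("<I", len(payload)) + payload
        if len(payload) % 2:
            data += b"\x00"
        return data

    def list_chunk(kind: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", kind + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(chunk(b"00db", _encode_frame(f)) for f in frames)
    movi = list_chunk(b"movi", movi_payload)

    # idx1: one entry per frame, offsets relative to the start of 'movi' fourcc
    idx_entries = []
    offset = 4
    padded = frame_size + (frame_size % 2)
    for _ in range(n):
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, offset, frame_size))
        offset += 8 + padded
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path):
    """Read an uncompressed-DIB AVI. Returns (frames array, fps)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise ValueError(f"{path}: not a RIFF/AVI file")

    width = height = bits = None
    fps = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start, end):
        nonlocal width, height, bits, fps
        for fcc, data_off, size in _iter_chunks(buf, start, end):
            if fcc == b"LIST":
                kind = buf[data_off:data_off + 4]
                if kind in (b"hdrl", b"strl", b"movi"):
                    if kind == b"movi":
                        for f2, off2, sz2 in _iter_chunks(buf, data_off + 4, data_off + size):
                            if f2[2:4] in (b"db", b"dc"):
                                frame_chunks.append((off2, sz2))
                    else:
                        walk(data_off + 4, data_off + size)
            elif fcc == b"strh":
                fcc_type = buf[data_off:data_off + 4]
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<II", buf, data_off + 20)
                    if scale:
                        fps = rate / scale
            elif fcc == b"strf" and width is None:
                _, w, h, _, bc, comp = struct.unpack_from("<IiiHHI", buf, data_off)
                if comp != 0:
                    raise ValueError(
                        f"{path}: compressed AVI stream (fourcc {comp:#x}) is not "
                        "supported; only uncompressed BI_RGB DIB frames are readable"
                    )
                width, height, bits = w, abs(h), bc
            elif fcc == b"avih" and fps is None:
                (usec,) = struct.unpack_from("<I", buf, data_off)
                if usec:
                    fps = 1e6 / usec

    walk(12, len(buf))
    if width is None:
        raise ValueError(f"{path}: no video stream header found")
    if bits not in (8, 24):
        raise ValueError(f"{path}: {bits}-bit DIB frames are not supported")
    bpp = bits // 8
    stride = (width * bpp + 3) & ~3

    frames = []
    for off, size in frame_chunks:
        if size < stride * height:
            continue  # skip drop-frame placeholders
        raw = np.frombuffer(buf, dtype=np.uint8, count=stride * height, offset=off)
        rows = raw.reshape(height, stride)[:, : width * bpp]
        if bpp == 1:
            frames.append(rows[::-1].copy())
        else:
            frames.append(rows.reshape(height, width, 3)[::-1, :, ::-1].copy())
    if not frames:
        raise ValueError(f"{path}: no decodable frames")
    return np.stack(frames), float(fps if fps else 0.0)
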