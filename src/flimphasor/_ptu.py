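"""Minimal PicoQuant .ptu (TTTR T3) container support.

Implements the published PTU structure: the ``PQTTTR`` magic, a tagged
header of 48-byte entries (32-char identifier, index, type code, 8-byte
value) terminated by ``Header_End``, followed by 32-bit PicoHarp-T3 records

    channel(4 bits) | dtime(12 bits) | nsync(16 bits)

``channel == 15`` flags special records: ``dtime == 0`` is a sync-counter
overflow (+65536), otherwise ``dtime`` carries external marker bits. Images
are encoded with frame and line-start/line-stop markers; photons inside a
line are assigned to pixels by their sync-count position between the two
line markers, which is the standard laser-scanning reconstruction.
"""

from __future__ import annotations

import os
import struct

import numpy as np

MAGIC = b"PQTTTR\x00\x00"
VERSION = b"1.0.00\x00\x00"

TY_EMPTY8 = 0xFFFF0008
TY_INT8 = 0x10000008
TY_FLOAT8 = 0x20000008

RT_PICOHARP_T3 = 0x00010303

_OVERFLOW_SYNCS = 65536


class PtuFormatError(ValueError):
    """Raised for files that are not valid (minimal) PTU containers."""


def _tag_bytes(ident: str, typ: int, value) -> bytes:
    ident_b = ident.encode("ascii").ljust(32, b"\x00")
    if typ == TY_INT8:
        val = struct.pack("<q", int(value))
    elif typ == TY_FLOAT8:
        val = struct.pack("<d", float(value))
    elif typ == TY_EMPTY8:
        val = struct.pack("<q", 0)
    else:  # pragma: no cover - writer emits only the above
        raise ValueError(f"unsupported tag type 0x{typ:08X}")
    return ident_b + struct.pack("<i", -1) + struct.pack("<I", typ) + val


def _records_from_cube(
    counts: np.ndarray, channel: int, dwell_syncs: int, marker_line_start: int,
    marker_line_stop: int, marker_frame: int,
) -> list[tuple[int, int, int]]:
    """(global_sync, channel, dtime) triples; channel -1 encodes a marker
    whose bits are in dtime."""
    rows, cols, _ = counts.shape
    events: list[tuple[int, int, int]] = []
    sync = 0
    events.append((sync, -1, 1 << (marker_frame - 1)))
    sync += 1
    for _r in range(rows):
        line_start = sync
        events.append((line_start, -1, 1 << (marker_line_start - 1)))
        for c in range(cols):
            # all photons of a pixel sit mid-dwell: unambiguous assignment
            t = line_start + 1 + c * dwell_syncs + dwell_syncs // 2
            row_counts = counts[_r, c]
            for dtime in np.nonzero(row_counts)[0]:
                events.extend(
                    (t, channel, int(dtime)) for _ in range(int(row_counts[dtime]))
                )
        sync = line_start + 1 + cols * dwell_syncs + 1
        events.append((sync, -1, 1 << (marker_line_stop - 1)))
        sync += 1
    return events


def write_ptu(
    path: str | os.PathLike,
    counts: np.ndarray,
    bin_width_ns: float,
    rep_rate_mhz: float,
    channel: int = 0,
    dwell_syncs: int = 8,
) -> None:
    """Write a (rows, cols, bins) cube as a PicoHarp-T3 image PTU."""
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError("counts must be (rows, cols, bins)")
    if counts.shape[2] > 4096:
        raise ValueError("PicoHarp T3 dtime is 12 bits: at most 4096 bins")
    rows, cols, _ = counts.shape
    mk_start, mk_stop, mk_frame = 1, 2, 3
    events = _records_from_cube(
        counts, channel + 1, dwell_syncs, mk_start, mk_stop, mk_frame
    )

    records: list[int] = []
    overflows = 0
    for global_sync, ch, dtime in events:
        while global_sync - overflows * _OVERFLOW_SYNCS >= _OVERFLOW_SYNCS:
            records.append((15 << 28) | 0)  # overflow record
            overflows += 1
        nsync = global_sync - overflows * _OVERFLOW_SYNCS
        rec_ch = 15 if ch == -1 else ch
        records.append((rec_ch << 28) | ((dtime & 0xFFF) << 16) | nsync)

    tags = b"".join(
        [
            _tag_bytes("TTResultFormat_TTTRRecType", TY_INT8, RT_PICOHARP_T3),
            _tag_bytes("TTResult_NumberOfRecords", TY_INT8, len(records)),
            _tag_bytes("MeasDesc_Resolution", TY_FLOAT8, bin_width_ns * 1e-9),
            _tag_bytes(
                "MeasDesc_GlobalResolution", TY_FLOAT8, 1.0 / (rep_rate_mhz * 1e6)
            ),
            _tag_bytes("ImgHdr_PixX", TY_INT8, cols),
            _tag_bytes("ImgHdr_PixY", TY_INT8, rows),
            _tag_bytes("ImgHdr_LineStart", TY_INT8, mk_start),
            _tag_bytes("ImgHdr_LineStop", TY_INT8, mk_stop),
            _tag_bytes("ImgHdr_Frame", TY_INT8, mk_frame),
            _tag_bytes("Header_End", TY_EMPTY8, 0),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(VERSION)
        fh.write(tags)
        fh.write(np.asarray(records, dtype="<u4").tobytes())


def read_header(raw: bytes, path) -> tuple[dict, int]:
    """Parse the tagged header; returns (tags, offset of first record)."""
    if raw[:8] != MAGIC:
        raise PtuFormatError(f"{path}: not a PTU file (bad magic)")
    pos = 16
    tags: dict[str, object] = {}
    while True:
        if pos + 48 > len(raw):
            raise PtuFormatError(f"{path}: header not terminated by Header_End")
        ident = raw[pos : pos + 32].rstrip(b"\x00").decode("ascii", "replace")
        typ = struct.unpack_from("<I", raw, pos + 36)[0]
        if typ == TY_INT8:
            value: object = struct.unpack_from("<q", raw, pos + 40)[0]
        elif typ == TY_FLOAT8:
            value = struct.unpack_from("<d", raw, pos + 40)[0]
        elif typ == TY_EMPTY8:
            value = None
        else:
            raise PtuFormatError(
                f"{path}: unsupported tag type 0x{typ:08X} for tag {ident!r}"
            )
        pos += 48
        if ident == "Header_End":
            return tags, pos
        tags[ident] = value


def _require(tags: dict, name: str, path) -> object:
    if name not in tags:
        raise PtuFormatError(f"{path}: required PTU tag {name!r} is absent")
    return tags[name]


def read_ptu_raw(
    path: str | os.PathLike, channel: int = 0
) -> tuple[np.ndarray, float, float]:
    """Decode a T3 image PTU; returns (counts, bin_width_ns, rep_rate_mhz).

    Photon records on other detector channels are ignored; multiple frames
    accumulate into the same histogram.
    """
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise PtuFormatError(f"cannot read PTU file {path}: {exc}") from exc
    tags, pos = read_header(raw, path)
    rec_type = _require(tags, "TTResultFormat_TTTRRecType", path)
    if rec_type != RT_PICOHARP_T3:
        raise PtuFormatError(
            f"{path}: unsupported TTTR record type 0x{rec_type:08X}"
        )
    resolution = float(_require(tags, "MeasDesc_Resolution", path))
    global_res = float(_require(tags, "MeasDesc_GlobalResolution", path))
    pix_x = int(_require(tags, "ImgHdr_PixX", path))
    pix_y = int(_require(tags, "ImgHdr_PixY", path))
    mk_start = int(_require(tags, "ImgHdr_LineStart", path))
    mk_stop = int(_require(tags, "ImgHdr_LineStop", path))
    if resolution <= 0 or global_res <= 0:
        raise PtuFormatError(f"{path}: non-positive timing resolution tags")

    n_bins = int(round(global_res / resolution))
    records = np.frombuffer(raw, dtype="<u4", offset=pos)
    nsync = (records & 0xFFFF).astype(np.int64)
    dtime = ((records >> 16) & 0xFFF).astype(np.int64)
    rec_ch = (records >> 28).astype(np.int64)

    special = rec_ch == 15
    overflow = special & (dtime == 0)
    global_sync = nsync + _OVERFLOW_SYNCS * np.cumsum(overflow) - np.where(
        overflow, _OVERFLOW_SYNCS, 0
    )

    counts = np.zeros((pix_y, pix_x, n_bins), dtype=np.uint32)
    is_marker = special & (dtime != 0)
    is_photon = ~special & (rec_ch == channel + 1)

    line = -1
    line_start_sync = 0
    pending: list[int] = []  # indices of photons in the open line
    start_bit, stop_bit = 1 << (mk_start - 1), 1 << (mk_stop - 1)
    for i in np.nonzero(is_marker | is_photon)[0]:
        if is_photon[i]:
            if line >= 0:
                pending.append(i)
            continue
        bits = int(dtime[i])
        if bits & start_bit:
            line += 1
            line_start_sync = int(global_sync[i])
            pending = []
        if (bits & stop_bit) and line >= 0 and 0 <= line % pix_y < pix_y:
            span = int(global_sync[i]) - line_start_sync
            if span > 0 and pending:
                idx = np.asarray(pending)
                px = ((global_sync[idx] - line_start_sync) * pix_x) // span
                px = np.clip(px, 0, pix_x - 1)
                dt = np.minimum(dtime[idx], n_bins - 1)
                np.add.at(counts, (line % pix_y, px, dt), 1)
            pending = []
    return counts, resolution * 1e9, 1.0 / global_res / 1e6
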