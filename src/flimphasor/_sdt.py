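"""Minimal Becker & Hickl .sdt container support.

Implements the subset of the SDT layout needed to round-trip image-mode
TCSPC histograms: the standard 42-byte file header, one measurement
description block per channel, and a chain of uncompressed uint16 data
blocks. The measurement-description template below is a documented minimal
layout (the vendor struct has hundreds of fields); files written here are
read back by :func:`read_sdt_raw`, which validates the header magic and the
field offsets it relies on.

Layout (little-endian throughout):

* file header: revision, offsets/lengths of info, setup, data and
  measurement-description sections, ``header_valid`` magic ``0x5555``.
* measurement description (one per channel): ``tac_r`` (TAC range, s),
  ``tac_g`` (TAC gain), ``adc_re`` (ADC resolution = number of time bins),
  ``scan_x``/``scan_y`` (image size), ``rep_rate`` (laser rate, MHz).
  Time-bin width = ``tac_r / tac_g / adc_re`` seconds, as in vendor files.
* data blocks: 22-byte block header (number, data offset, next-block offset,
  type, measurement-description index, long block number, byte length)
  followed by row-major ``(scan_y, scan_x, adc_re)`` uint16 counts.
"""

from __future__ import annotations

import os

import numpy as np

HEADER_VALID = 0x5555
_BLOCK_TYPE_U16 = 1

FILE_HEADER = np.dtype(
    [
        ("revision", "<i2"),
        ("info_offs", "<i4"),
        ("info_length", "<i2"),
        ("setup_offs", "<i4"),
        ("setup_length", "<u2"),
        ("data_block_offs", "<i4"),
        ("no_of_data_blocks", "<i2"),
        ("data_block_length", "<u4"),
        ("meas_desc_block_offs", "<i4"),
        ("no_of_meas_desc_blocks", "<i2"),
        ("meas_desc_block_length", "<i2"),
        ("header_valid", "<u2"),
        ("reserved1", "<u4"),
        ("reserved2", "<u2"),
        ("chksum", "<u2"),
    ]
)

MEAS_DESC = np.dtype(
    [
        ("tac_r", "<f4"),  # TAC range in seconds
        ("tac_g", "<i2"),  # TAC gain divider
        ("adc_re", "<i2"),  # ADC resolution: number of time bins
        ("scan_x", "<i4"),  # columns
        ("scan_y", "<i4"),  # rows
        ("rep_rate", "<f4"),  # laser repetition rate, MHz
    ]
)

BLOCK_HEADER = np.dtype(
    [
        ("block_no", "<i2"),
        ("data_offs", "<i4"),
        ("next_block_offs", "<i4"),
        ("block_type", "<u2"),
        ("meas_desc_block_no", "<i2"),
        ("lblock_no", "<u4"),
        ("block_length", "<u4"),
    ]
)

_INFO = b"SDT minimal image container\r\n"


class SdtFormatError(ValueError):
    """Raised for files that are not valid (minimal) SDT containers."""


def write_sdt(
    path: str | os.PathLike,
    cubes: list[np.ndarray],
    bin_width_ns: float,
    rep_rate_mhz: float,
) -> None:
    """Write one data block per channel cube (rows, cols, bins) as uint16."""
    cubes = [np.ascontiguousarray(c) for c in cubes]
    for c in cubes:
        if c.ndim != 3:
            raise ValueError("each channel cube must be (rows, cols, bins)")
        if c.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed uint16 range of the SDT container")

    n_ch = len(cubes)
    header = np.zeros(1, dtype=FILE_HEADER)[0]
    pos = FILE_HEADER.itemsize
    header["revision"] = 0x0F
    header["info_offs"] = pos
    header["info_length"] = len(_INFO)
    pos += len(_INFO)
    header["setup_offs"] = pos
    header["setup_length"] = 0
    header["meas_desc_block_offs"] = pos
    header["no_of_meas_desc_blocks"] = n_ch
    header["meas_desc_block_length"] = MEAS_DESC.itemsize
    pos += n_ch * MEAS_DESC.itemsize
    header["data_block_offs"] = pos
    header["no_of_data_blocks"] = n_ch
    header["data_block_length"] = max(c.size * 2 for c in cubes)
    header["header_valid"] = HEADER_VALID

    meas = np.zeros(n_ch, dtype=MEAS_DESC)
    for i, c in enumerate(cubes):
        rows, cols, nbins = c.shape
        meas[i]["tac_g"] = 1
        meas[i]["adc_re"] = nbins
        meas[i]["tac_r"] = bin_width_ns * 1e-9 * nbins  # tac_r / tac_g / adc_re
        meas[i]["scan_x"] = cols
        meas[i]["scan_y"] = rows
        meas[i]["rep_rate"] = rep_rate_mhz

    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(_INFO)
        fh.write(meas.tobytes())
        offs = pos
        for i, c in enumerate(cubes):
            data = c.astype("<u2").tobytes()
            bh = np.zeros(1, dtype=BLOCK_HEADER)[0]
            bh["block_no"] = i
            bh["data_offs"] = offs + BLOCK_HEADER.itemsize
            next_offs = offs + BLOCK_HEADER.itemsize + len(data)
            bh["next_block_offs"] = next_offs if i + 1 < n_ch else 0
            bh["block_type"] = _BLOCK_TYPE_U16
            bh["meas_desc_block_no"] = i
            bh["lblock_no"] = i
            bh["block_length"] = len(data)
            fh.write(bh.tobytes())
            fh.write(data)
            offs = next_offs


def read_sdt_raw(
    path: str | os.PathLike, channel: int = 0
) -> tuple[np.ndarray, float, float]:
    """Read one channel; returns (counts, bin_width_ns, rep_rate_mhz)."""
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise SdtFormatError(f"cannot read SDT file {path}: {exc}") from exc
    if len(raw) < FILE_HEADER.itemsize:
        raise SdtFormatError(f"{path}: too short to be an SDT file")
    header = np.frombuffer(raw, dtype=FILE_HEADER, count=1)[0]
    if header["header_valid"] != HEADER_VALID:
        raise SdtFormatError(
            f"{path}: invalid SDT header magic "
            f"0x{int(header['header_valid']):04X} (expected 0x{HEADER_VALID:04X})"
        )
    n_meas = int(header["no_of_meas_desc_blocks"])
    n_blocks = int(header["no_of_data_blocks"])
    if not 0 <= channel < n_blocks:
        raise SdtFormatError(
            f"{path}: channel {channel} out of range; available channels: "
            f"{list(range(n_blocks))}"
        )
    if int(header["meas_desc_block_length"]) != MEAS_DESC.itemsize:
        raise SdtFormatError(
            f"{path}: unsupported measurement-description length "
            f"{int(header['meas_desc_block_length'])}"
        )
    meas = np.frombuffer(
        raw, dtype=MEAS_DESC, count=n_meas, offset=int(header["meas_desc_block_offs"])
    )

    offs = int(header["data_block_offs"])
    for i in range(n_blocks):
        bh = np.frombuffer(raw, dtype=BLOCK_HEADER, count=1, offset=offs)[0]
        if i == channel:
            if bh["block_type"] != _BLOCK_TYPE_U16:
                raise SdtFormatError(
                    f"{path}: unsupported data block type {int(bh['block_type'])}"
                )
            m = meas[int(bh["meas_desc_block_no"])]
            rows, cols, nbins = int(m["scan_y"]), int(m["scan_x"]), int(m["adc_re"])
            n_expected = rows * cols * nbins
            data = np.frombuffer(
                raw, dtype="<u2", count=n_expected, offset=int(bh["data_offs"])
            )
            if data.size != n_expected:
                raise SdtFormatError(f"{path}: truncated data block {i}")
            bin_width_ns = float(m["tac_r"]) / float(m["tac_g"]) / nbins * 1e9
            return (
                data.reshape(rows, cols, nbins).astype(np.uint32),
                bin_width_ns,
                float(m["rep_rate"]),
            )
        offs = int(bh["next_block_offs"])
        if offs <= 0:
            break
    raise SdtFormatError(f"{path}: data block chain ended before channel {channel}")
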