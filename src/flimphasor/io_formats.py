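"""Readers and writers for decay cubes, masks, condition tables and results.

Supported inputs: Becker & Hickl ``.sdt``, PicoQuant ``.ptu`` (TTTR T3
image mode) and multi-page ``.tif`` stacks (one page per time bin — these
carry no timing metadata, so the bin width must be supplied). Outputs:
32-bit float single-page TIFF lifetime maps (masked pixels NaN) and RFC-4180
CSV summary tables.

Images are indexed (row, col) with row 0 at the top.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import _ptu, _sdt
from .model import DecayCube, LifetimeMaps, SummaryRecord

__all__ = [
    "FormatError",
    "read_decay",
    "read_sdt",
    "read_ptu",
    "read_tif_stack",
    "write_tif_stack",
    "read_intensity_mask",
    "read_condition_table",
    "write_outputs",
    "SUMMARY_COLUMNS",
]

# "scope" (image | roi | condition) comes last so the leading columns stay stable
SUMMARY_COLUMNS = [
    "sample_id",
    "condition",
    "n_pixels",
    "n_photons",
    "mean_tau_phase_ns",
    "mean_tau_mod_ns",
    "mean_tau_avg_ns",
    "scope",
]


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


def read_sdt(path: str | os.PathLike, channel: int = 0) -> DecayCube:
    """Read one channel of a Becker & Hickl .sdt file."""
    try:
        counts, bin_width, rep_rate = _sdt.read_sdt_raw(path, channel)
    except _sdt.SdtFormatError as exc:
        raise FormatError(str(exc)) from exc
    return DecayCube(
        counts=counts,
        bin_width=bin_width,
        rep_frequency=rep_rate,
        source_path=str(path),
        channel=channel,
    )


def read_ptu(path: str | os.PathLike, channel: int = 0) -> DecayCube:
    """Read a PicoQuant .ptu image file, binning TTTR photon records.

    Photons are histogrammed per pixel using the file's line markers and
    resolution tags; a missing tag raises :class:`FormatError` naming it.
    """
    try:
        counts, bin_width, rep_rate = _ptu.read_ptu_raw(path, channel)
    except _ptu.PtuFormatError as exc:
        raise FormatError(str(exc)) from exc
    return DecayCube(
        counts=counts,
        bin_width=bin_width,
        rep_frequency=rep_rate,
        source_path=str(path),
        channel=channel,
    )


def read_tif_stack(
    path: str | os.PathLike,
    bin_width: float | None = None,
    rep_frequency: float = 80.0,
) -> DecayCube:
    """Read a multi-page TIFF, one page per time bin.

    TIFF stacks carry no TCSPC metadata, so ``bin_width`` (ns) is mandatory.
    Page order is time order. Float pages with integral values are cast
    losslessly to integers.
    """
    if bin_width is None:
        raise FormatError(
            f"{path}: bin width (ns) is required for .tif input; this format "
            "lacks timing metadata"
        )
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read TIFF: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(
            f"{path}: expected a stack of 2-D pages, got shape {pages.shape}"
        )
    counts = np.moveaxis(pages, 0, -1)  # (bin, row, col) -> (row, col, bin)
    if np.issubdtype(counts.dtype, np.floating):
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded, atol=1e-6):
            raise FormatError(f"{path}: float TIFF counts are not integral")
        counts = rounded
    counts = counts.astype(np.uint32)
    return DecayCube(
        counts=counts,
        bin_width=float(bin_width),
        rep_frequency=float(rep_frequency),
        source_path=str(path),
    )


def write_tif_stack(path: str | os.PathLike, cube: DecayCube) -> None:
    """Write a cube as a multi-page uint16 TIFF (page index = time bin)."""
    counts = np.rint(np.asarray(cube.counts, dtype=np.float64)).astype(np.uint16)
    tifffile.imwrite(path, np.moveaxis(counts, -1, 0), photometric="minisblack")


def read_decay(
    path: str | os.PathLike,
    channel: int = 0,
    bin_width: float | None = None,
    rep_frequency: float | None = None,
) -> DecayCube:
    """Dispatch on the file extension (.sdt / .ptu / .tif / .tiff)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".sdt":
        cube = read_sdt(path, channel)
    elif suffix == ".ptu":
        cube = read_ptu(path, channel)
    elif suffix in (".tif", ".tiff"):
        cube = read_tif_stack(path, bin_width, rep_frequency or 80.0)
    else:
        raise FormatError(f"{path}: unsupported decay format {suffix!r}")
    if rep_frequency is not None and suffix not in (".tif", ".tiff"):
        cube.rep_frequency = float(rep_frequency)
    return cube


def read_intensity_mask(path: str | os.PathLike, shape: tuple[int, int]) -> np.ndarray:
    """Read a binary pixel mask image; nonzero pixels are included."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse color/alpha channels
        img = img.max(axis=-1)
    if img.shape != tuple(shape):
        raise FormatError(
            f"{path}: mask shape {img.shape} does not match image shape {tuple(shape)}"
        )
    return img != 0


def read_condition_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a sample -> condition table.

    Two columns (``file_path``, ``condition``) or three (with a leading
    ``sample_id``). Sample ids default to file stems and must be unique;
    every file path must exist.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "file_path" not in cols or "condition" not in cols:
        raise FormatError(
            f"{path}: condition table needs 'file_path' and 'condition' columns, "
            f"got {cols}"
        )
    if "sample_id" not in cols:
        df["sample_id"] = [Path(p).stem for p in df["file_path"]]
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"{path}: duplicate sample_id values: {dupes}")
    base = Path(path).parent
    missing = []
    resolved = []
    for p in df["file_path"]:
        candidate = Path(p)
        if not candidate.is_absolute():
            candidate = base / candidate
        if not candidate.exists():
            missing.append(str(p))
        resolved.append(str(candidate))
    if missing:
        raise FormatError(f"{path}: listed files do not exist: {missing}")
    df["file_path"] = resolved
    return df[["sample_id", "file_path", "condition"]]


def _map_to_float32(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.asarray(values, dtype=np.float32).copy()
    out[~valid] = np.nan
    return out


def write_outputs(
    maps: LifetimeMaps | None,
    summaries: list[SummaryRecord],
    out_dir: str | os.PathLike,
    sample_id: str = "sample",
    per_pixel: pd.DataFrame | None = None,
) -> list[Path]:
    """Write lifetime maps (float32 TIFF, invalid pixels NaN) and the
    summary CSV; returns the created paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    if maps is not None:
        for which in ("phase", "mod", "avg"):
            arr, valid = maps.map_for(which)
            p = out / f"{sample_id}_tau_{which}.tif"
            tifffile.imwrite(p, _map_to_float32(arr, valid))
            written.append(p)
    csv_path = out / "summary.csv"
    rows = [r.as_row() for r in summaries]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(csv_path, index=False, lineterminator="\r\n", float_format="%.6f")
    written.append(csv_path)
    if per_pixel is not None:
        pp_path = out / "per_pixel.csv"
        per_pixel.to_csv(pp_path, index=False, lineterminator="\r\n")
        written.append(pp_path)
    return written
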