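"""Masking, phasor-space ROI selection, summaries and condition pooling."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.stats import mannwhitneyu

from .model import LifetimeMaps, PhasorField, PhasorROI, SummaryRecord

__all__ = [
    "select_by_phasor_roi",
    "exclude_pixels",
    "summarize",
    "pool_condition",
    "pooled_points_dataframe",
    "mann_whitney",
    "load_rois",
]


def select_by_phasor_roi(field: PhasorField, roi: PhasorROI) -> np.ndarray:
    """Pixels whose calibrated (g, s) lies inside the ROI.

    Boundary-inclusive; only pixels valid in ``field`` are eligible. A
    zero-area ROI yields an empty mask with a warning.
    """
    mask = np.zeros(field.shape, dtype=bool)
    pts = np.column_stack([field.g[field.valid], field.s[field.valid]])
    if roi.kind == "polygon":
        verts = roi.params
        # shoelace area; degenerate (collinear) polygons select nothing
        x, y = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        )
        if area == 0.0:
            warnings.warn(f"ROI {roi.label!r} has zero area; empty selection")
            return mask
        path = MplPath(verts)
        # matplotlib's inclusion test is boundary-exclusive for some edges;
        # a tiny positive radius makes it inclusive within float jitter
        inside = path.contains_points(pts, radius=1e-9) | path.contains_points(
            pts, radius=-1e-9
        )
    elif roi.kind == "ellipse":
        cg, cs, a, b, angle = roi.params
        ca, sa = np.cos(angle), np.sin(angle)
        dx, dy = pts[:, 0] - cg, pts[:, 1] - cs
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12
    else:  # pragma: no cover - PhasorROI validates kind
        raise ValueError(f"unknown ROI kind {roi.kind!r}")
    mask[field.valid] = inside
    return mask


def exclude_pixels(mask: np.ndarray, exclusion: np.ndarray) -> np.ndarray:
    """``mask AND NOT exclusion`` — drop manually flagged pixels."""
    mask = np.asarray(mask, dtype=bool)
    exclusion = np.asarray(exclusion, dtype=bool)
    if mask.shape != exclusion.shape:
        raise ValueError(
            f"mask shape {mask.shape} != exclusion shape {exclusion.shape}"
        )
    return mask & ~exclusion


def summarize(
    maps: LifetimeMaps,
    field: PhasorField,
    mask: np.ndarray | None,
    sample_id: str,
    condition: str,
    scope: str = "image",
) -> SummaryRecord:
    """Pixel-weighted mean lifetimes over ``mask`` (AND per-map validity).

    Each valid pixel counts once, regardless of its photon total: downstream
    statistics operate on per-image means, so pixels are the unit here.
    Empty selections produce a record with ``n_pixels = 0`` and no means.
    """
    if mask is None:
        mask = np.ones(maps.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {maps.shape}")

    def _mean(values: np.ndarray, valid: np.ndarray) -> float | None:
        sel = mask & valid
        return float(values[sel].mean()) if sel.any() else None

    sel_any = mask & field.valid
    return SummaryRecord(
        sample_id=sample_id,
        condition=condition,
        scope=scope,
        n_pixels=int((mask & maps.valid).sum()),
        n_photons=int(field.photons[sel_any].sum()) if sel_any.any() else 0,
        mean_tau_phase=_mean(maps.tau_phase, maps.valid_phase),
        mean_tau_mod=_mean(maps.tau_mod, maps.valid_mod),
        mean_tau_avg=_mean(maps.tau_avg, maps.valid),
    )


def pool_condition(
    fields: list[PhasorField],
    masks: list[np.ndarray | None],
    condition: str,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate masked valid (g, s) points of one condition.

    No re-weighting across images: every pixel contributes one point, tagged
    with its source sample. All fields must share the same omega.
    """
    if not fields:
        raise ValueError("pool_condition needs at least one field")
    omega0 = fields[0].omega
    for f in fields[1:]:
        if not np.isclose(f.omega, omega0, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"omega mismatch across pooled fields: {f.omega} vs {omega0}"
            )
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(len(fields))]
    frames = []
    for fld, msk, sid in zip(fields, masks, sample_ids):
        pts = fld.masked_points(msk)
        frames.append(
            pd.DataFrame(
                {
                    "g": pts[:, 0],
                    "s": pts[:, 1],
                    "sample_id": sid,
                    "condition": condition,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pooled_points_dataframe(pools: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-condition pools into one exportable table."""
    return pd.concat(pools, ignore_index=True)


def mann_whitney(
    group_a: "list[float] | np.ndarray", group_b: "list[float] | np.ndarray"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-image means.

    Exact null distribution for small tie-free groups (n <= 8 each), normal
    approximation with tie correction otherwise — scipy's ``method='auto'``
    policy, which matches that convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def load_rois(path: str | Path) -> list[PhasorROI]:
    """Load ROI definitions from JSON.

    Schema: a list of objects with ``kind`` ("polygon" | "ellipse"),
    ``label`` and either ``vertices`` ([[g, s], ...]) or ``center``,
    ``semi_axes``, ``angle``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    rois = []
    for entry in raw:
        kind = entry["kind"]
        if kind == "polygon":
            params = np.asarray(entry["vertices"], dtype=float)
        else:
            cg, cs = entry["center"]
            a, b = entry["semi_axes"]
            params = np.array([cg, cs, a, b, float(entry.get("angle", 0.0))])
        rois.append(PhasorROI(kind=kind, params=params, label=entry.get("label", "")))
    return rois
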