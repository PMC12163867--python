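"""Static rendering: phasor plots, lifetime/intensity maps, galleries, violins.

All figures are rendered with the non-interactive Agg backend and are
deterministic for identical inputs (no unseeded jitter anywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy.stats import gaussian_kde

from .model import LifetimeMaps, SummaryRecord

__all__ = [
    "PlotStyle",
    "universal_circle",
    "render_phasor_plot",
    "render_lifetime_map",
    "render_intensity_map",
    "render_gallery",
    "violin_data",
]

logger = logging.getLogger(__name__)

_GALLERY_COLS = 3
_CONTOUR_LEVELS = (0.25, 0.50, 0.75, 0.95)  # fractions of peak KDE density
_HIST_BINS = 200
_PHASOR_XLIM = (-0.005, 1.005)
_PHASOR_YLIM = (0.0, 0.7)


@dataclass
class PlotStyle:
    """Rendering options shared by the plot functions."""

    mode: str = "contour"  # scatter | histogram2d | contour
    colormap: str = "viridis"
    lifetime_range: tuple[float, float] | None = None  # ns color limits
    point_alpha: float = 0.5
    condition_colors: dict[str, str] = field(default_factory=dict)
    highlight_color: str = "#ff4fc3"
    dpi: int = 300

    def __post_init__(self) -> None:
        if self.mode not in ("scatter", "histogram2d", "contour"):
            raise ValueError(f"unknown plot mode {self.mode!r}")
        if self.lifetime_range is not None and not (
            self.lifetime_range[0] < self.lifetime_range[1]
        ):
            raise ValueError(f"empty lifetime_range {self.lifetime_range}")
        if not 0.0 <= self.point_alpha <= 1.0:
            raise ValueError("point_alpha must be in [0, 1]")

    def color_for(self, condition: str, index: int) -> str:
        if condition in self.condition_colors:
            return self.condition_colors[condition]
        cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        return cycle[index % len(cycle)]


def universal_circle(n_vertices: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of the upper semicircle g^2 + s^2 = g (single exponentials)."""
    theta = np.linspace(0.0, np.pi, n_vertices)
    return 0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta)


def _draw_circle(ax) -> None:
    cx, cy = universal_circle()
    ax.plot(cx, cy, color="0.3", lw=1.0, zorder=1)


def render_phasor_plot(
    point_sets: list[pd.DataFrame],
    style: PlotStyle,
    out_path: str | Path,
) -> Path:
    """Phasor-cloud figure: one layer per condition over the universal circle.

    ``point_sets`` are pooled-condition tables with ``g``, ``s`` and
    ``condition`` columns (as produced by ``analysis.pool_condition``).
    Contour mode draws Gaussian-KDE iso-density lines (Scott's bandwidth) at
    25/50/75/95% of the peak; histogram2d uses a fixed 200x200 grid.
    """
    fig, ax = plt.subplots(figsize=(6, 4.5))
    _draw_circle(ax)
    for i, pts in enumerate(point_sets):
        if len(pts) == 0:
            logger.warning("empty phasor point set at index %d; circle only", i)
            continue
        cond = str(pts["condition"].iloc[0]) if "condition" in pts else f"set {i}"
        color = style.color_for(cond, i)
        g = np.asarray(pts["g"], dtype=float)
        s = np.asarray(pts["s"], dtype=float)
        if style.mode == "scatter":
            ax.scatter(g, s, s=2, alpha=style.point_alpha, color=color, label=cond,
                       linewidths=0)
        elif style.mode == "histogram2d":
            h, xe, ye = np.histogram2d(
                g, s, bins=_HIST_BINS, range=[[0.0, 1.0], [0.0, 0.7]]
            )
            hm = np.ma.masked_equal(h.T, 0)
            ax.pcolormesh(xe, ye, hm, cmap=style.colormap, zorder=2)
        else:  # contour
            if len(g) < 3 or (np.ptp(g) == 0 and np.ptp(s) == 0):
                ax.scatter(g, s, s=4, color=color, label=cond)
                continue
            kde = gaussian_kde(np.vstack([g, s]))  # Scott's rule default
            gx = np.linspace(0.0, 1.0, 200)
            gy = np.linspace(0.0, 0.7, 140)
            mx, my = np.meshgrid(gx, gy)
            dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(mx.shape)
            levels = [f * dens.max() for f in _CONTOUR_LEVELS]
            ax.contour(mx, my, dens, levels=levels, colors=color, linewidths=1.2)
            ax.plot([], [], color=color, label=cond)
    ax.set_xlim(*_PHASOR_XLIM)
    ax.set_ylim(*_PHASOR_YLIM)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="upper right", frameon=False, fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return out_path


def _color_limits(values: np.ndarray, valid: np.ndarray, style: PlotStyle):
    if style.lifetime_range is not None:
        return style.lifetime_range
    vals = values[valid]
    if vals.size == 0:
        return (0.0, 1.0)
    lo, hi = np.percentile(vals, [2.0, 98.0])
    if lo >= hi:
        hi = lo + max(abs(lo) * 1e-6, 1e-6)
    return float(lo), float(hi)


def render_lifetime_map(
    maps: LifetimeMaps,
    which: str,
    style: PlotStyle,
    out_path: str | Path,
    highlight: np.ndarray | None = None,
    title: str | None = None,
) -> Path:
    """Color-coded lifetime image with an ns colorbar.

    Invalid pixels render as the background (black); ``highlight`` pixels
    override the colormap with the style's accent color (ROI back-mapping).
    """
    values, valid = maps.map_for(which)
    vmin, vmax = _color_limits(values, valid, style)
    cmap = colormaps[style.colormap].copy()
    cmap.set_bad("black")
    shown = np.ma.masked_invalid(np.where(valid, values, np.nan))
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(shown, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    if highlight is not None and highlight.any():
        hl = np.ma.masked_where(~highlight, np.ones_like(values))
        from matplotlib.colors import ListedColormap

        ax.imshow(hl, cmap=ListedColormap([style.highlight_color]),
                  interpolation="nearest")
    fig.colorbar(im, ax=ax, label=f"tau_{which} (ns)")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return out_path


def render_intensity_map(
    intensity: np.ndarray, style: PlotStyle, out_path: str | Path,
    title: str | None = None,
) -> Path:
    """Photon-count image (grayscale) with a colorbar."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(intensity, cmap="gray", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="photons")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return out_path


def render_gallery(
    items: list[tuple[str, np.ndarray, np.ndarray]],
    kind: str,
    style: PlotStyle,
    out_path: str | Path,
) -> Path:
    """Grid of per-sample maps: ``items`` are (sample_id, values, valid).

    Lifetime galleries share one color scale across every panel (global
    limits over all valid pixels); intensity galleries are per-panel scaled.
    Layout: 3 columns, ceil(n / 3) rows.
    """
    if not items:
        raise ValueError("gallery needs at least one item")
    n = len(items)
    ncols = min(_GALLERY_COLS, n)
    nrows = int(np.ceil(n / _GALLERY_COLS))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    if kind == "lifetime":
        if style.lifetime_range is not None:
            vmin, vmax = style.lifetime_range
        else:
            all_vals = np.concatenate(
                [v[valid] for _, v, valid in items if valid.any()] or [np.zeros(1)]
            )
            vmin, vmax = (
                np.percentile(all_vals, [2.0, 98.0]) if all_vals.size else (0.0, 1.0)
            )
            if vmin >= vmax:
                vmax = vmin + 1e-6
        cmap = colormaps[style.colormap].copy()
        cmap.set_bad("black")
    last_im = None
    for idx, (sid, values, valid) in enumerate(items):
        ax = axes[idx // _GALLERY_COLS][idx % _GALLERY_COLS]
        if kind == "lifetime":
            shown = np.ma.masked_invalid(np.where(valid, values, np.nan))
            last_im = ax.imshow(
                shown, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest"
            )
        else:
            last_im = ax.imshow(values, cmap="gray", interpolation="nearest")
        ax.set_title(sid, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    for idx in range(n, nrows * ncols):
        axes[idx // _GALLERY_COLS][idx % _GALLERY_COLS].axis("off")
    if kind == "lifetime" and last_im is not None:
        fig.colorbar(last_im, ax=axes, shrink=0.8, label="tau (ns)")
    else:
        fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return out_path


def violin_data(
    summaries: list[SummaryRecord],
    metric: str,
    out_path: str | Path | None = None,
    style: PlotStyle | None = None,
) -> dict[str, list[float]]:
    """Per-condition per-image means, optionally rendered as violins.

    Returns ``{condition: [values...]}`` (insertion-ordered), so external
    statistics can reproduce the figure exactly. Median and quartile lines
    use NumPy's linear-interpolation quantiles. Conditions with no usable
    records are skipped with a warning.
    """
    attr = {
        "phase": "mean_tau_phase",
        "mod": "mean_tau_mod",
        "avg": "mean_tau_avg",
    }[metric]
    groups: dict[str, list[float]] = {}
    for rec in summaries:
        val = getattr(rec, attr)
        if val is None:
            continue
        groups.setdefault(rec.condition, []).append(float(val))
    empty = [c for c, vals in groups.items() if not vals]
    for c in empty:
        logger.warning("condition %r has no records; skipped", c)
        del groups[c]

    if out_path is not None and groups:
        style = style or PlotStyle()
        fig, ax = plt.subplots(figsize=(1.2 + 1.3 * len(groups), 4))
        data = list(groups.values())
        parts = ax.violinplot(
            data, showmeans=False, showmedians=False, showextrema=False
        )
        for i, (cond, vals) in enumerate(groups.items()):
            body = parts["bodies"][i]
            body.set_facecolor(style.color_for(cond, i))
            body.set_alpha(0.6)
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            ax.hlines([q1, q3], i + 0.85, i + 1.15, color="0.2", lw=0.8)
            ax.hlines(med, i + 0.8, i + 1.2, color="0.1", lw=1.6)
            jitter_x = np.linspace(-0.08, 0.08, len(vals))  # deterministic
            ax.scatter(i + 1 + jitter_x, sorted(vals), s=10, color="0.25", zorder=3)
        ax.set_xticks(range(1, len(groups) + 1), list(groups))
        ax.set_ylabel(f"tau_{metric} (ns)")
        fig.tight_layout()
        fig.savefig(out_path, dpi=style.dpi)
        plt.close(fig)
    return groups
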