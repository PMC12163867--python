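"""Core data structures shared across the package.

Conventions
-----------
* Images are indexed ``(row, col)`` with row 0 at the top, matching the usual
  display orientation of the source microscopy software.
* Time-bin centers are at ``t_k = (k + 0.5) * bin_width`` nanoseconds.
* All lifetimes are in nanoseconds; repetition frequencies in MHz; the
  angular frequency ``omega`` is in rad/ns (``2 * pi * f_GHz * harmonic``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecayCube",
    "PhasorField",
    "CalibrationTransform",
    "LifetimeMaps",
    "SummaryRecord",
    "PhasorROI",
]


@dataclass
class DecayCube:
    """Per-pixel photon arrival-time histograms.

    Parameters
    ----------
    counts : ndarray, shape (rows, cols, n_bins)
        Non-negative photon counts. File readers always produce integer
        arrays; noiseless synthetic cubes may carry float expected counts.
        Photon totals are accumulated in 64 bits downstream.
    bin_width : float
        Width of one time bin in nanoseconds.
    rep_frequency : float
        Laser repetition rate in MHz.
    source_path : str
        Origin of the data, for reporting.
    channel : int
        Detector/measurement channel the cube was read from.
    """

    counts: np.ndarray
    bin_width: float
    rep_frequency: float
    source_path: str = ""
    channel: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(
                f"counts must be (rows, cols, bins), got shape {self.counts.shape}"
            )
        if np.issubdtype(self.counts.dtype, np.floating) and not np.all(
            np.isfinite(self.counts)
        ):
            raise ValueError("counts contain non-finite values")
        if self.counts.min(initial=0) < 0:
            raise ValueError("negative photon counts")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if self.rep_frequency <= 0:
            raise ValueError(
                f"rep_frequency must be > 0, got {self.rep_frequency}"
            )
        period = 1000.0 / self.rep_frequency  # ns
        window = self.n_bins * self.bin_width
        if window > period + self.bin_width:
            warnings.warn(
                f"measurement window {window:.4g} ns exceeds the laser period "
                f"{period:.4g} ns (+1 bin tolerance); check bin_width / frequency",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def period(self) -> float:
        """Laser period in ns."""
        return 1000.0 / self.rep_frequency

    def bin_centers(self) -> np.ndarray:
        """Time-bin centers in ns: ``(k + 0.5) * bin_width``."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals, overflow-safe for pooling.

        Integer cubes accumulate in int64; float (synthetic expected-count)
        cubes in float64.
        """
        if np.issubdtype(self.counts.dtype, np.floating):
            return self.counts.sum(axis=2, dtype=np.float64)
        return self.counts.sum(axis=2, dtype=np.int64)


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    photons: np.ndarray
    valid: np.ndarray
    harmonic: int
    omega: float  # rad/ns

    def __post_init__(self) -> None:
        if self.harmonic < 1:
            raise ValueError(f"harmonic must be >= 1, got {self.harmonic}")
        if not (self.g.shape == self.s.shape == self.photons.shape == self.valid.shape):
            raise ValueError("phasor component shapes disagree")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape

    def masked_points(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid (g, s) pairs, optionally restricted by an extra mask.

        Returns an (n, 2) float array.
        """
        sel = self.valid if mask is None else (self.valid & mask.astype(bool))
        return np.column_stack([self.g[sel], self.s[sel]])


@dataclass(frozen=True)
class CalibrationTransform:
    """Rotation + modulation-scale correction from a reference dye.

    Applying the transform rotates every phasor by ``delta_phi`` and scales
    its modulus by ``mod_scale`` so that the reference lands on its
    theoretical single-exponential position.
    """

    delta_phi: float
    mod_scale: float
    tau_ref: float
    omega: float

    def __post_init__(self) -> None:
        if self.mod_scale <= 0:
            raise ValueError(f"mod_scale must be > 0, got {self.mod_scale}")
        if not abs(self.delta_phi) < np.pi:
            raise ValueError(f"|delta_phi| must be < pi, got {self.delta_phi}")

    def inverse(self) -> "CalibrationTransform":
        return CalibrationTransform(
            delta_phi=-self.delta_phi,
            mod_scale=1.0 / self.mod_scale,
            tau_ref=self.tau_ref,
            omega=self.omega,
        )


@dataclass
class LifetimeMaps:
    """Per-pixel phase, modulation and average lifetimes (ns).

    Each map carries its own validity mask because the phase and modulation
    lifetimes can degenerate independently (``M >= 1`` vs ``phi <= 0``).
    ``valid`` is the conjunction of the per-map masks.
    """

    tau_phase: np.ndarray
    tau_mod: np.ndarray
    tau_avg: np.ndarray
    valid: np.ndarray
    valid_phase: np.ndarray | None = None
    valid_mod: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid_phase is None:
            self.valid_phase = self.valid
        if self.valid_mod is None:
            self.valid_mod = self.valid

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau_phase.shape

    def map_for(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(map, validity)`` for 'phase' | 'mod' | 'avg'."""
        try:
            return {
                "phase": (self.tau_phase, self.valid_phase),
                "mod": (self.tau_mod, self.valid_mod),
                "avg": (self.tau_avg, self.valid),
            }[which]
        except KeyError:
            raise ValueError(
                f"unknown lifetime map {which!r}; expected phase|mod|avg"
            ) from None


@dataclass
class SummaryRecord:
    """Mean lifetimes over one image, ROI, or pooled condition."""

    sample_id: str
    condition: str
    scope: str  # image | roi | condition
    n_pixels: int
    n_photons: int
    mean_tau_phase: float | None
    mean_tau_mod: float | None
    mean_tau_avg: float | None

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "condition": self.condition,
            "scope": self.scope,
            "n_pixels": self.n_pixels,
            "n_photons": self.n_photons,
            "mean_tau_phase_ns": self.mean_tau_phase,
            "mean_tau_mod_ns": self.mean_tau_mod,
            "mean_tau_avg_ns": self.mean_tau_avg,
        }


@dataclass
class PhasorROI:
    """A region in (g, s) phasor space, polygon or ellipse.

    For polygons ``params`` is an (n >= 3, 2) vertex array. For ellipses it
    is ``(cg, cs, semi_g, semi_s, angle_rad)``.
    """

    kind: str  # "polygon" | "ellipse"
    params: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    label: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.kind == "polygon":
            if self.params.ndim != 2 or self.params.shape[0] < 3 or self.params.shape[1] != 2:
                raise ValueError("polygon ROI needs >= 3 (g, s) vertices")
        elif self.kind == "ellipse":
            if self.params.shape != (5,):
                raise ValueError(
                    "ellipse ROI params are (cg, cs, semi_g, semi_s, angle)"
                )
            if self.params[2] <= 0 or self.params[3] <= 0:
                raise ValueError("ellipse semi-axes must be > 0")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
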