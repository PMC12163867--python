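"""Phasor transform, reference calibration and lifetime maps.

The per-pixel transform projects each decay histogram onto the cosine/sine
basis at the laser's (harmonic) angular frequency:

    G = sum_k I(t_k) cos(w t_k) / sum_k I(t_k)
    S = sum_k I(t_k) sin(w t_k) / sum_k I(t_k)

with ``t_k`` the bin centers and ``w = 2 pi f n`` in rad/ns. Calibration
rotates and rescales the raw phasors so that a measured single-exponential
reference dye of known lifetime lands on its theoretical position on the
universal circle; this cancels the instrument response and timing offsets
without deconvolution.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import median_filter

from .model import CalibrationTransform, DecayCube, LifetimeMaps, PhasorField

__all__ = [
    "omega_rad_per_ns",
    "compute_phasor",
    "derive_calibration",
    "apply_calibration",
    "lifetimes_from_phasor",
    "apply_photon_threshold",
    "spatial_bin",
    "median_filter_phasor",
    "theoretical_phasor",
]

logger = logging.getLogger(__name__)


def omega_rad_per_ns(rep_frequency_mhz: float, harmonic: int = 1) -> float:
    """Angular frequency in rad/ns for a repetition rate in MHz."""
    return 2.0 * np.pi * (rep_frequency_mhz * 1e-3) * harmonic


def theoretical_phasor(tau: float, omega: float) -> tuple[float, float]:
    """(g, s) of an ideal single-exponential lifetime ``tau`` at ``omega``.

    Lies on the universal circle: g = 1/(1+(wt)^2), s = wt/(1+(wt)^2).
    """
    wt = omega * tau
    d = 1.0 + wt * wt
    return 1.0 / d, wt / d


def compute_phasor(cube: DecayCube, harmonic: int = 1) -> PhasorField:
    """Per-pixel phasor coordinates of a decay cube.

    Pixels with zero photons are marked invalid (their g/s are NaN).

    Raises
    ------
    ValueError
        If ``harmonic < 1``.
    """
    if harmonic < 1:
        raise ValueError(f"harmonic must be a positive integer, got {harmonic}")
    omega = omega_rad_per_ns(cube.rep_frequency, harmonic)
    t = cube.bin_centers()
    cos_t = np.cos(omega * t)
    sin_t = np.sin(omega * t)
    counts = cube.counts.astype(np.float64)
    total = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ cos_t / total
        s = counts @ sin_t / total
    valid = total > 0
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(
        g=g,
        s=s,
        photons=cube.total_counts(),
        valid=valid,
        harmonic=harmonic,
        omega=omega,
    )


def derive_calibration(ref_field: PhasorField, tau_ref: float) -> CalibrationTransform:
    """Rotation/scale correction from a measured single-exponential reference.

    The photon-weighted mean phasor of the valid reference pixels is compared
    with the theoretical position of a ``tau_ref`` single exponential; the
    returned transform maps the former onto the latter.
    """
    if tau_ref <= 0:
        raise ValueError(f"tau_ref must be > 0, got {tau_ref}")
    if not ref_field.valid.any():
        raise ValueError("reference field has no valid pixels")
    w = ref_field.photons[ref_field.valid].astype(np.float64)
    g_mean = np.average(ref_field.g[ref_field.valid], weights=w)
    s_mean = np.average(ref_field.s[ref_field.valid], weights=w)
    m_meas = float(np.hypot(g_mean, s_mean))
    if m_meas == 0.0:
        raise ValueError("degenerate reference: mean phasor modulus is zero")
    phi_meas = float(np.arctan2(s_mean, g_mean))

    omega = ref_field.omega
    wt = omega * tau_ref
    phi_theo = float(np.arctan(wt))
    m_theo = 1.0 / float(np.sqrt(1.0 + wt * wt))

    delta_phi = phi_theo - phi_meas
    # wrap into (-pi, pi]
    delta_phi = float(np.arctan2(np.sin(delta_phi), np.cos(delta_phi)))
    return CalibrationTransform(
        delta_phi=delta_phi,
        mod_scale=m_theo / m_meas,
        tau_ref=tau_ref,
        omega=omega,
    )


def apply_calibration(field: PhasorField, cal: CalibrationTransform) -> PhasorField:
    """Rotate by ``delta_phi`` then scale by ``mod_scale``; returns a new field."""
    if not np.isclose(field.omega, cal.omega, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"omega mismatch: field at {field.omega} rad/ns, "
            f"calibration at {cal.omega} rad/ns"
        )
    c, s_ = np.cos(cal.delta_phi), np.sin(cal.delta_phi)
    g_new = cal.mod_scale * (field.g * c - field.s * s_)
    s_new = cal.mod_scale * (field.g * s_ + field.s * c)
    return PhasorField(
        g=g_new,
        s=s_new,
        photons=field.photons,
        valid=field.valid.copy(),
        harmonic=field.harmonic,
        omega=field.omega,
    )


def lifetimes_from_phasor(field: PhasorField) -> LifetimeMaps:
    """Phase, modulation and average lifetime maps from calibrated phasors.

    tau_phase = tan(phi) / omega with phi = atan2(s, g);
    tau_mod   = sqrt(1/M^2 - 1) / omega with M = hypot(g, s);
    tau_avg   = (tau_phase + tau_mod) / 2.

    Degenerate pixels do not raise: where ``M >= 1`` the modulation lifetime
    is invalid, where ``phi <= 0`` the phase lifetime is invalid (zero phase,
    i.e. tau = 0 exactly at (1, 0), stays valid). The counts of degenerate
    pixels are logged.
    """
    omega = field.omega
    phi = np.arctan2(field.s, field.g)
    m2 = field.g**2 + field.s**2

    at_pole = field.valid & np.isclose(field.g, 1.0) & np.isclose(field.s, 0.0)
    valid_phase = field.valid & ((phi > 0) | at_pole)
    valid_mod = field.valid & ((m2 < 1.0) | at_pole)

    with np.errstate(invalid="ignore", divide="ignore"):
        tau_phase = np.tan(phi) / omega
        tau_mod = np.sqrt(np.maximum(1.0 / m2 - 1.0, 0.0)) / omega
    tau_phase[at_pole] = 0.0
    tau_mod[at_pole] = 0.0
    tau_phase[~valid_phase] = np.nan
    tau_mod[~valid_mod] = np.nan

    valid = valid_phase & valid_mod
    tau_avg = 0.5 * (tau_phase + tau_mod)
    tau_avg[~valid] = np.nan

    n_deg_phase = int((field.valid & ~valid_phase).sum())
    n_deg_mod = int((field.valid & ~valid_mod).sum())
    if n_deg_phase or n_deg_mod:
        logger.info(
            "degenerate pixels: %d with non-positive phase, %d with M >= 1",
            n_deg_phase,
            n_deg_mod,
        )
    return LifetimeMaps(
        tau_phase=tau_phase,
        tau_mod=tau_mod,
        tau_avg=tau_avg,
        valid=valid,
        valid_phase=valid_phase,
        valid_mod=valid_mod,
    )


def apply_photon_threshold(
    cube: DecayCube, min_photons: int = 0, max_photons: int | None = None
) -> np.ndarray:
    """Boolean mask of pixels whose photon total is within [min, max].

    Both bounds are inclusive; ``max_photons=None`` means no upper bound.
    """
    if min_photons < 0:
        raise ValueError(f"min_photons must be >= 0, got {min_photons}")
    if max_photons is not None and max_photons <= min_photons:
        raise ValueError(
            f"max_photons ({max_photons}) must exceed min_photons ({min_photons})"
        )
    total = cube.total_counts()
    mask = total >= min_photons
    if max_photons is not None:
        mask &= total <= max_photons
    return mask


def spatial_bin(cube: DecayCube, bin_radius: int) -> DecayCube:
    """Sliding-window sum of decays over (2r+1)^2 neighborhoods.

    The spatial shape is preserved (no downsampling); windows are truncated
    at the image edges. ``bin_radius=0`` returns an identical copy. The sum
    is computed exactly on int64 via a 2-D summed-area table.
    """
    if bin_radius < 0:
        raise ValueError(f"bin_radius must be >= 0, got {bin_radius}")
    if bin_radius == 0:
        return DecayCube(
            counts=cube.counts.copy(),
            bin_width=cube.bin_width,
            rep_frequency=cube.rep_frequency,
            source_path=cube.source_path,
            channel=cube.channel,
        )
    is_float = np.issubdtype(cube.counts.dtype, np.floating)
    acc_dtype = np.float64 if is_float else np.int64
    counts = cube.counts.astype(acc_dtype)
    rows, cols, nbins = counts.shape
    # summed-area table with a zero border
    sat = np.zeros((rows + 1, cols + 1, nbins), dtype=acc_dtype)
    np.cumsum(counts, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    r = bin_radius
    r0 = np.clip(np.arange(rows) - r, 0, rows)
    r1 = np.clip(np.arange(rows) + r + 1, 0, rows)
    c0 = np.clip(np.arange(cols) - r, 0, cols)
    c1 = np.clip(np.arange(cols) + r + 1, 0, cols)
    out = (
        sat[r1[:, None], c1[None, :]]
        - sat[r0[:, None], c1[None, :]]
        - sat[r1[:, None], c0[None, :]]
        + sat[r0[:, None], c0[None, :]]
    )
    return DecayCube(
        counts=out if is_float else out.astype(np.uint64),
        bin_width=cube.bin_width,
        rep_frequency=cube.rep_frequency,
        source_path=cube.source_path,
        channel=cube.channel,
    )


def median_filter_phasor(field: PhasorField, passes: int = 1) -> PhasorField:
    """Optional k-pass 3x3 median smoothing of the g and s maps.

    Off by default in the pipeline; provided for noisy data. Invalid pixels
    are left untouched.
    """
    g, s = field.g.copy(), field.s.copy()
    for _ in range(passes):
        g_f = median_filter(np.nan_to_num(g), size=3, mode="nearest")
        s_f = median_filter(np.nan_to_num(s), size=3, mode="nearest")
        g[field.valid] = g_f[field.valid]
        s[field.valid] = s_f[field.valid]
    return PhasorField(
        g=g,
        s=s,
        photons=field.photons,
        valid=field.valid.copy(),
        harmonic=field.harmonic,
        omega=field.omega,
    )
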