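"""Scattering-amplitude spectrum of the nucleus arrangement.

The arrangement of nuclei inside an embryo is modelled as identical
repeating units: the scattering potential is F(r) = F₀(r) ∗ Σₙ δ(r − rₙ),
so its Fourier transform factorizes into a form function (the transform of
one unit) times the structure function S(q) = Σₙ exp(i rₙ·q).  Replacing
every nucleus with a unit sphere at its centroid removes the size/shape
variability, leaving the spatial distribution of the nuclei as the only
signal.  The model volume is a 256³ grid; the radially averaged power
spectral density over 256 |k| shells yields the half-power bandwidth
``bw3dB`` (rad·µm⁻¹), the spatial frequency at which the power first
drops to 50% of its peak — a compact arrangement of few nuclei spreads
power over a wider band than a dispersed arrangement of many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft

logger = logging.getLogger(__name__)

GRID = 256


@dataclass
class PointModelVolume:
    """Binary unit-sphere point model on a cubic FFT grid."""

    field: np.ndarray  # (grid, grid, grid) float32 of {0, 1}
    spacing_um: tuple[float, float, float]  # physical µm per grid voxel (z, y, x)
    n_points: int
    n_overlaps: int = 0


@dataclass
class ScatteringSpectrum:
    """Radially averaged power spectral density of the scattering amplitude."""

    k: np.ndarray  # 256 radial spatial-frequency levels (rad / µm)
    power: np.ndarray  # shell-averaged |F(q)|²
    peak_power: float
    bw3db: float  # rad / µm
    bw3db_flagged: bool = False  # True when the power never crossed half-peak

    @property
    def bin_width(self) -> float:
        return float(self.k[1] - self.k[0])


def _unit_sphere_offsets(radius_vox: float = 1.0) -> np.ndarray:
    """Voxel offsets within Euclidean distance ``radius_vox`` of the centre.

    For the default radius of one voxel this is the 6-neighbourhood ball
    (centre plus face neighbours, 7 voxels).
    """
    r = int(np.ceil(radius_vox))
    g = np.arange(-r, r + 1)
    Z, Y, X = np.meshgrid(g, g, g, indexing="ij")
    keep = Z * Z + Y * Y + X * X <= radius_vox * radius_vox
    return np.stack([Z[keep], Y[keep], X[keep]], axis=1)


def build_point_model(
    centroids_um: np.ndarray,
    volume_extent_um: tuple[float, float, float],
    grid: int = GRID,
    sphere_radius_vox: float = 1.0,
    z_pitch_um: float = 1.0,
) -> PointModelVolume:
    """Map centroids into a ``grid³`` volume and stamp unit spheres.

    ``centroids_um`` is (n, 3) in (z, y, x) µm within a volume of physical
    size ``volume_extent_um``.  The lateral axes are downsized so their
    extent fills the grid (spacing = extent / grid); the z axis keeps the
    acquisition pitch (default 1 µm) and is zero-padded to the grid
    length, which samples the low radial frequencies finely along kz —
    without the padding the first |k| shells would contain no frequency
    samples at all and the half-power bandwidth would degenerate to a
    constant.  If the z extent exceeds ``grid × z_pitch_um`` the pitch is
    enlarged to fit (logged).  The per-axis frequency grids are rescaled
    by the resulting anisotropic spacings when the spectrum is computed.
    Overlapping spheres merge (union semantics) and are logged.
    """
    cents = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if cents.shape[0] < 1 or cents.shape[1] != 3:
        raise ValueError("need at least one (z, y, x) centroid")
    extent = np.asarray(volume_extent_um, dtype=float)
    if np.any(cents < 0) or np.any(cents > extent):
        raise ValueError("centroid outside the volume extent")
    if extent[0] > grid * z_pitch_um:
        z_pitch_um = extent[0] / grid
        logger.info("z extent %.1f µm exceeds the padded axis; pitch -> %.3f µm",
                    extent[0], z_pitch_um)
    spacing = np.array([z_pitch_um, extent[1] / grid, extent[2] / grid])
    idx = np.clip((cents / spacing).astype(int), 0, grid - 1)

    field = np.zeros((grid, grid, grid), dtype=np.float32)
    offsets = _unit_sphere_offsets(sphere_radius_vox)
    occupied: set[tuple[int, int, int]] = set()
    overlaps = 0
    for c in idx:
        key = tuple(int(v) for v in c)
        if key in occupied:
            overlaps += 1
        occupied.add(key)
        pts = np.clip(c + offsets, 0, grid - 1)
        field[pts[:, 0], pts[:, 1], pts[:, 2]] = 1.0
    if overlaps:
        logger.info("%d centroid(s) mapped onto occupied grid voxels", overlaps)
    return PointModelVolume(field, tuple(spacing), n_points=len(cents), n_overlaps=overlaps)


def compute_spectrum(model: PointModelVolume) -> ScatteringSpectrum:
    """3D FFT power spectrum, shell-averaged into 256 radial |k| bins.

    The forward transform is unnormalized (Σ f(r) e^{−i q·r}); per-axis
    angular frequencies are 2π·fftfreq(n, d=spacing) so |k| is in
    rad·µm⁻¹.  Bin 0 holds the DC term alone; the remaining range up to
    max|k| is divided into 255 equal shells (membership by half-open
    interval (k_{j−1}, k_j]).
    """
    field = model.field
    if not field.any():
        raise ValueError("point model is empty")
    grid = field.shape[0]
    # double precision keeps the power spectrum translation-invariant to
    # better than 1e-9 relative
    power = np.abs(scipy.fft.fftn(field.astype(np.float64), workers=-1)) ** 2

    freqs = [
        (2.0 * np.pi * np.fft.fftfreq(n, d=d)).astype(np.float32)
        for n, d in zip(field.shape, model.spacing_um)
    ]
    kmag = np.sqrt(
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    kmax = float(kmag.max())
    levels = np.linspace(0.0, kmax, grid)
    # shell index: 0 for DC only, then (k_{j-1}, k_j] -> j
    step = kmax / (grid - 1)
    shell = np.ceil(kmag.ravel() / step - 1e-6).astype(np.int64)
    np.clip(shell, 0, grid - 1, out=shell)
    sums = np.bincount(shell, weights=power.ravel(), minlength=grid)
    counts = np.bincount(shell, minlength=grid)
    radial = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    peak = float(radial.max())
    bw, flagged = _bandwidth_3db(levels, radial, peak)
    return ScatteringSpectrum(levels, radial, peak, bw, flagged)


def _bandwidth_3db(k: np.ndarray, p: np.ndarray, peak: float) -> tuple[float, bool]:
    half = 0.5 * peak
    i_peak = int(np.argmax(p))
    for i in range(i_peak + 1, len(p)):
        if p[i] <= half:
            # linear interpolation between the straddling bins
            k0, k1 = k[i - 1], k[i]
            p0, p1 = p[i - 1], p[i]
            if p1 == p0:
                return float(k1), False
            return float(k0 + (p0 - half) / (p0 - p1) * (k1 - k0)), False
    logger.warning("power never drops to half-peak; bw3dB set to max |k|")
    return float(k[-1]), True


def bandwidth_3db(spectrum: ScatteringSpectrum) -> float:
    """Half-power (3 dB) bandwidth of a spectrum, in rad·µm⁻¹."""
    return spectrum.bw3db


def bandwidth_from_profile(k: np.ndarray, power: np.ndarray) -> tuple[float, bool]:
    """Half-power bandwidth of an arbitrary radial profile.

    Returns ``(bw3dB, flagged)``; the bandwidth is the smallest k past the
    peak at which the power first falls to ≤ 50% of the peak, linearly
    interpolated between the straddling bins.  When the power never drops
    below half-peak the maximum k is returned with ``flagged=True``.
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(power, dtype=float)
    peak = float(p.max())
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("power profile must have a finite positive peak")
    return _bandwidth_3db(k, p, peak)


def spectrum_from_centroids(
    centroids_um: np.ndarray,
    volume_extent_um: tuple[float, float, float],
    grid: int = GRID,
) -> ScatteringSpectrum:
    """Convenience: point model + spectrum in one call."""
    return compute_spectrum(build_point_model(centroids_um, volume_extent_um, grid))
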