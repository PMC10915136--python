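"""Per-nucleus structural and compositional features.

Dry mass follows the quantitative-phase relation

    M = λ / (2πγ) · ∫ φ(r) d³r            [pg]

with λ the illumination wavelength (µm), γ the refractive-index increment
expressed in µm³/pg and φ the measured phase in radians; dry-mass density
is ρ = M / V.  Shape descriptors (volume, triangulated-isosurface area,
sphericity) are computed on the isotropically resampled label volume.
Nuclei are assigned to the trophectoderm (TE) or inner-cell-mass (ICM)
compartment by thresholding the normalized radial position of their
centroid within the embryo.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .glim import PhaseVolume
from .link3d import LabelVolume

logger = logging.getLogger(__name__)

#: normalized-radius threshold separating TE (outside) from ICM (inside)
TE_RADIUS_THRESHOLD = 0.7

#: Gaussian std-dev in voxels used by the smoothed-isosurface area estimator
SURFACE_SMOOTHING_SIGMA = 0.6


def dry_mass(phase: PhaseVolume, mask: np.ndarray) -> float:
    """Dry mass (pg) of the region ``mask`` of a calibrated phase volume.

    Implements M = λ/(2πγ) Σ φ(r) · v_voxel over the mask.  Negative
    results are allowed (noise-dominated regions) but logged.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != phase.phi.shape:
        raise ValueError("mask shape does not match the phase volume")
    if not m.any():
        raise ValueError("empty mask")
    total_phi = float(phase.phi[m].sum(dtype=np.float64))
    mass = (
        phase.wavelength_um
        / (2.0 * np.pi * phase.gamma_um3_per_pg)
        * total_phi
        * phase.voxel_volume_um3
    )
    if mass < 0:
        logger.warning("negative dry mass (%.3g pg): noise-dominated region", mass)
    return mass


def shape_features(
    mask: np.ndarray, voxel_size_um: float | tuple[float, float, float]
) -> tuple[float, float, float]:
    """Volume (µm³), surface area (µm²) and sphericity of a binary mask.

    Volume is voxel count × voxel volume.  Surface area is the area of the
    triangulated isosurface at level 0.5 of the mask smoothed with a
    Gaussian of σ = 0.6 voxel (the smoothing suppresses the voxelization
    staircase so that digitized spheres measure sphericity ≈ 1 instead of
    ≈ 0.92).  Sphericity is π^{1/3}(6V)^{2/3} / S, i.e. the area of the
    equal-volume sphere over the measured area.  A mask touching the
    volume border is still measured (logged); expect a truncated surface.
    """
    m = np.asarray(mask, dtype=bool)
    if isinstance(voxel_size_um, (int, float)):
        spacing = (float(voxel_size_um),) * 3
    else:
        spacing = tuple(float(v) for v in voxel_size_um)
    if not m.any():
        raise ValueError("empty mask")
    if (
        m[0].any() or m[-1].any()
        or m[:, 0].any() or m[:, -1].any()
        or m[:, :, 0].any() or m[:, :, -1].any()
    ):
        logger.warning("mask touches the volume border; surface area is truncated")
    volume = float(m.sum()) * spacing[0] * spacing[1] * spacing[2]
    smoothed = ndi.gaussian_filter(m.astype(np.float32), SURFACE_SMOOTHING_SIGMA)
    if smoothed.max() <= 0.5:
        # object too thin for the smoothing (e.g. a single voxel): fall
        # back to the raw binary isosurface
        smoothed = m.astype(np.float32)
    padded = np.pad(smoothed, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface = float(measure.mesh_surface_area(verts, faces))
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface
    return volume, surface, sphericity


def build_records(
    labels: LabelVolume, phase: PhaseVolume, drop_high_sphericity: bool = True
) -> pd.DataFrame:
    """One feature row per labelled nucleus.

    Columns: id, centroid_{z,y,x}_um, volume_um3, surface_um2, sphericity,
    dry_mass_pg, dmd_pg_um3 (= M/V exactly).  Records with sphericity > 1
    (under-segmented clusters) are dropped with a logged count.  Expects
    co-registered, isotropically resampled volumes.
    """
    if labels.labels.shape != phase.phi.shape:
        raise ValueError("label and phase volumes have different shapes")
    lab = labels.labels
    spacing = labels.voxel_size_um
    rows = []
    objects = ndi.find_objects(lab)
    for idx, sl in enumerate(objects):
        if sl is None:
            continue
        label_id = idx + 1
        # pad the crop by 1 voxel so the isosurface closes
        sl = tuple(
            slice(max(0, s.start - 1), min(dim, s.stop + 1))
            for s, dim in zip(sl, lab.shape)
        )
        crop = lab[sl] == label_id
        vol, surf, sph = shape_features(crop, spacing)
        phase_crop = PhaseVolume(
            phase.phi[sl],
            dx_um=phase.dx_um,
            dz_um=phase.dz_um,
            wavelength_um=phase.wavelength_um,
            gamma_um3_per_pg=phase.gamma_um3_per_pg,
        )
        mass = dry_mass(phase_crop, crop)
        zz, yy, xx = np.nonzero(crop)
        origin = np.array([s.start for s in sl], dtype=float)
        cz, cy, cx = (
            (origin + np.array([zz.mean(), yy.mean(), xx.mean()]) + 0.5)
            * np.array(spacing)
        )
        rows.append(
            dict(
                id=label_id,
                centroid_z_um=cz,
                centroid_y_um=cy,
                centroid_x_um=cx,
                volume_um3=vol,
                surface_um2=surf,
                sphericity=sph,
                dry_mass_pg=mass,
                dmd_pg_um3=mass / vol,
            )
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "id", "centroid_z_um", "centroid_y_um", "centroid_x_um",
            "volume_um3", "surface_um2", "sphericity", "dry_mass_pg",
            "dmd_pg_um3",
        ],
    )
    if drop_high_sphericity and len(records):
        bad = records.sphericity > 1.0
        if bad.any():
            logger.info("dropping %d record(s) with sphericity > 1", int(bad.sum()))
        records = records[~bad].reset_index(drop=True)
    return records


def assign_compartment(
    records: pd.DataFrame, threshold: float = TE_RADIUS_THRESHOLD
) -> pd.DataFrame:
    """Add normalized_radius and compartment (TE/ICM) columns.

    The embryo centre is the centroid of the nucleus centroids and the
    radial scale the maximum centroid distance; nuclei strictly outside
    the normalized-radius threshold are TE, those at or inside it ICM
    (inclusive-inside convention).  A single nucleus gets normalized
    radius 0 (ICM).
    """
    if records.empty:
        raise ValueError("need at least one record")
    out = records.copy()
    cents = out[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    d = np.linalg.norm(cents - cents.mean(axis=0), axis=1)
    dmax = d.max()
    norm_r = d / dmax if dmax > 0 else np.zeros(len(out))
    out["normalized_radius"] = norm_r
    out["compartment"] = np.where(norm_r > threshold, "TE", "ICM")
    return out


def dmd_map(
    labels: LabelVolume, records: pd.DataFrame, sigma: tuple[float, float, float] = (1.0, 1.0, 3.0)
) -> tuple[np.ndarray, bool]:
    """Normalized mean dry-mass-density map.

    Every voxel of a nucleus is set to that nucleus's mean density, the
    volume is Gaussian filtered with σ = (1, 1, 3) in (x, y, z) — i.e.
    (3, 1, 1) in array (z, y, x) order — and divided by its maximum so
    values lie in [0, 1].  Returns ``(map, flagged)`` where ``flagged``
    marks an all-zero result (returned unchanged).
    """
    lut = np.zeros(int(labels.labels.max()) + 1, dtype=np.float32)
    for _, row in records.iterrows():
        if int(row.id) < len(lut):
            lut[int(row.id)] = row.dmd_pg_um3
    vol = lut[labels.labels]
    vol = ndi.gaussian_filter(vol, sigma=(sigma[2], sigma[1], sigma[0]))
    peak = float(vol.max())
    if peak <= 0:
        logger.warning("dry-mass-density map is empty")
        return vol, True
    return vol / peak, False


def embryo_features(
    records: pd.DataFrame, bw3db: float, embryo_id: str | int = 0
) -> dict:
    """Embryo-level aggregate summary (nucleus count + spectral bandwidth)."""
    return dict(
        embryo_id=embryo_id,
        nuc_count=int(len(records)),
        bw3dB=float(bw3db),
        mean_dmd_pg_um3=float(records.dmd_pg_um3.mean()) if len(records) else np.nan,
        mean_sphericity=float(records.sphericity.mean()) if len(records) else np.nan,
    )
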