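"""Synthetic embryo volumes with exact ground truth.

Emulates day-5 mouse embryos as imaged by a laser-scanning GLIM system
paired with a nucleus-channel predictor:

* a *phase* volume (radians): nuclear dry-mass signal obtained by inverting
  the dry-mass relation M = λ/(2πγ) ∫ φ d³r, plus a smooth low-amplitude
  cytoplasm blob and additive Gaussian noise;
* a *nucleus-channel* volume: intensity proportional to nuclear dry-mass
  density (a stand-in for a fluorescence stain or a nucleus-prediction
  network output), with a weak cytoplasmic leak and additive noise;
* a ground-truth table with one row per nucleus (centroid, volume, dry
  mass, dry-mass density, TE/ICM compartment), exact by construction.

Three embryo classes are modelled: expanded blastocysts (healthy /
intermediate) with many nuclei arranged as an outer trophectoderm (TE)
shell around an inner-cell-mass (ICM) core and a TE>ICM dry-mass-density
contrast, and growth-arrested cleavage-stage ("sick") embryos: compact
balls of few, often fragmented, low-sphericity nuclei with no
compartment contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .glim import PhaseVolume


class EmbryoClass(str, Enum):
    BLASTOCYST_HEALTHY = "blastocyst_healthy"
    BLASTOCYST_INTERMEDIATE = "blastocyst_intermediate"
    CLEAVAGE_SICK = "cleavage_sick"

    @property
    def health_label(self) -> str:
        """Embryologist-style grade: H, I or S."""
        return {
            EmbryoClass.BLASTOCYST_HEALTHY: "H",
            EmbryoClass.BLASTOCYST_INTERMEDIATE: "I",
            EmbryoClass.CLEAVAGE_SICK: "S",
        }[self]

    @property
    def binary_label(self) -> str:
        """Two-class grade used by the health classifier: HI or S."""
        return "S" if self is EmbryoClass.CLEAVAGE_SICK else "HI"


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass
class SynthConfig:
    """Full description of one synthetic embryo.

    Pixel-free (µm) geometry plus calibration; densities in pg·µm⁻³.
    ``noise_sd`` is additive Gaussian noise on the phase volume (radians);
    ``nucleus_noise_sd`` is additive noise on the nucleus channel relative
    to its unit peak (SNR = 1 / nucleus_noise_sd).
    """

    embryo_class: EmbryoClass = EmbryoClass.BLASTOCYST_HEALTHY
    n_nuclei: int = 48
    embryo_radius_um: float = 32.0
    nucleus_radius_um_range: tuple[float, float] = (2.6, 3.4)
    te_fraction: float = 0.30
    dmd_te_pg_per_um3: float = 0.125
    dmd_icm_pg_per_um3: float = 0.100
    density_rel_sd: float = 0.08
    fragmentation_prob: float = 0.0
    noise_sd: float = 0.02
    nucleus_noise_sd: float = 0.10
    min_separation_um: float = 2.0
    te_shell_range: tuple[float, float] = (0.78, 0.92)
    icm_core_radius: float = 0.60
    cyto_density_pg_um3: float = 0.04
    cyto_channel_level: float = 0.03
    axis_ratio_range: tuple[float, float] = (0.85, 1.0)
    margin_um: float = 2.0
    lateral_px_per_um: float = 11.0
    z_step_um: float = 1.0
    wavelength_um: float = 0.488
    gamma_um3_per_pg: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.embryo_class = EmbryoClass(self.embryo_class)
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_radius_um_range
        if not (0 < lo <= hi < self.embryo_radius_um):
            raise ValueError("nucleus radii must be positive and < embryo radius")
        if not 0.0 <= self.te_fraction <= 1.0:
            raise ValueError("te_fraction must be in [0, 1]")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.nucleus_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.lateral_px_per_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of the generated stacks."""
        half = self.embryo_radius_um + self.nucleus_radius_um_range[1] + self.margin_um
        nxy = int(math.ceil(2 * half * self.lateral_px_per_um))
        nz = int(math.ceil(2 * half / self.z_step_um))
        return nz, nxy, nxy

    def to_yaml(self, path) -> None:
        import dataclasses
        from pathlib import Path

        import yaml

        d = dataclasses.asdict(self)
        d["embryo_class"] = self.embryo_class.value
        d["nucleus_radius_um_range"] = list(self.nucleus_radius_um_range)
        d["te_shell_range"] = list(self.te_shell_range)
        d["axis_ratio_range"] = list(self.axis_ratio_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        from pathlib import Path

        import yaml

        d = yaml.safe_load(Path(path).read_text())
        for key in ("nucleus_radius_um_range", "te_shell_range", "axis_ratio_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Class presets: the study conditions the generator emulates.  Healthy and
# intermediate embryos are blastocysts (TE shell + ICM core, TE/ICM density
# contrast); sick embryos are growth-arrested compact balls with fewer,
# frequently fragmented nuclei and no compartment contrast.
CLASS_PRESETS: dict[EmbryoClass, dict] = {
    EmbryoClass.BLASTOCYST_HEALTHY: dict(
        n_nuclei_range=(40, 55),
        embryo_radius_um=32.0,
        nucleus_radius_um_range=(2.6, 3.4),
        te_fraction=0.30,
        dmd_te_pg_per_um3=0.125,
        dmd_icm_pg_per_um3=0.100,
        fragmentation_prob=0.0,
    ),
    EmbryoClass.BLASTOCYST_INTERMEDIATE: dict(
        n_nuclei_range=(24, 36),
        embryo_radius_um=28.0,
        nucleus_radius_um_range=(2.6, 3.4),
        te_fraction=0.28,
        dmd_te_pg_per_um3=0.130,
        dmd_icm_pg_per_um3=0.105,
        fragmentation_prob=0.10,
        icm_core_radius=0.62,
    ),
    EmbryoClass.CLEAVAGE_SICK: dict(
        n_nuclei_range=(6, 14),
        embryo_radius_um=20.0,
        nucleus_radius_um_range=(3.0, 4.0),
        te_fraction=0.0,
        dmd_te_pg_per_um3=0.120,
        dmd_icm_pg_per_um3=0.120,
        fragmentation_prob=0.45,
        icm_core_radius=0.85,
    ),
}


def default_config(
    embryo_class: EmbryoClass | str,
    seed: int,
    n_nuclei: int | None = None,
    **overrides,
) -> SynthConfig:
    """Build a :class:`SynthConfig` from the class presets.

    ``n_nuclei`` defaults to a draw from the class's preset range using a
    generator derived from ``seed`` (so a cohort of configs varies
    realistically while remaining reproducible).
    """
    cls = EmbryoClass(embryo_class)
    preset = dict(CLASS_PRESETS[cls])
    lo, hi = preset.pop("n_nuclei_range")
    if n_nuclei is None:
        n_nuclei = int(np.random.default_rng(seed ^ 0x5EED).integers(lo, hi + 1))
    preset.update(overrides)
    return SynthConfig(embryo_class=cls, n_nuclei=n_nuclei, seed=seed, **preset)


# ---------------------------------------------------------------------------
# placement and rasterization
# ---------------------------------------------------------------------------

def _place_centroids(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Random sequential placement of nucleus centres (µm, volume coords).

    TE nuclei sit on the outer shell, ICM nuclei in the core; sick embryos
    have te_fraction 0 and fill a compact ball.  Surface-to-surface
    separation of at least ``min_separation_um`` is enforced by bounded
    retries; failure raises :class:`PlacementError` with a diagnostic.
    """
    n = config.n_nuclei
    n_te = int(round(config.te_fraction * n))
    r_lo, r_hi = config.nucleus_radius_um_range
    R = config.embryo_radius_um
    nz, ny, nx = config.shape
    center = np.array(
        [nz * config.z_step_um / 2.0]
        + [ny / config.lateral_px_per_um / 2.0, nx / config.lateral_px_per_um / 2.0]
    )

    placed: list[np.ndarray] = []
    radii: list[float] = []
    comps: list[str] = []
    max_tries = 2000
    for i in range(n):
        is_te = i < n_te
        r_nuc = float(rng.uniform(r_lo, r_hi))
        for attempt in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if is_te:
                rad = R * rng.uniform(*config.te_shell_range)
            else:
                # uniform in a ball of radius icm_core_radius * R
                rad = R * config.icm_core_radius * rng.uniform() ** (1.0 / 3.0)
            pos = center + rad * direction
            if placed:
                gaps = np.linalg.norm(np.array(placed) - pos, axis=1)
                if np.any(gaps < np.array(radii) + r_nuc + config.min_separation_um):
                    continue
            placed.append(pos)
            radii.append(r_nuc)
            comps.append("TE" if is_te else "ICM")
            break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} (r={r_nuc:.2f} µm) after "
                f"{max_tries} tries; embryo radius {R} µm is too crowded"
            )
    return np.array(placed), comps, np.array(radii)


def _voxel_coords(config: SynthConfig):
    """Physical coordinates (µm) of voxel centres along each axis."""
    nz, ny, nx = config.shape
    z = (np.arange(nz) + 0.5) * config.z_step_um
    y = (np.arange(ny) + 0.5) / config.lateral_px_per_um
    x = (np.arange(nx) + 0.5) / config.lateral_px_per_um
    return z, y, x


def _stamp_ellipsoid(mask, zc, yc, xc, center, semi, config):
    """Set voxels inside an axis-aligned ellipsoid; returns the local slice."""
    cz, cy, cx = center
    sz, sy, sx = semi
    z0 = np.searchsorted(zc, cz - sz) ; z1 = np.searchsorted(zc, cz + sz) + 1
    y0 = np.searchsorted(yc, cy - sy) ; y1 = np.searchsorted(yc, cy + sy) + 1
    x0 = np.searchsorted(xc, cx - sx) ; x1 = np.searchsorted(xc, cx + sx) + 1
    zz = (zc[z0:z1, None, None] - cz) / sz
    yy = (yc[None, y0:y1, None] - cy) / sy
    xx = (xc[None, None, x0:x1] - cx) / sx
    inside = zz * zz + yy * yy + xx * xx <= 1.0
    mask[z0:z1, y0:y1, x0:x1] |= inside


def generate_embryo(config: SynthConfig):
    """Generate one synthetic embryo.

    Returns
    -------
    phase : PhaseVolume
        Calibrated phase stack (radians), nuclear signal + cytoplasm + noise.
    nucleus_channel : ndarray (nz, ny, nx) float32
        Nucleus-channel stack in [0, ~1] + noise.
    truth : pandas.DataFrame
        One row per nucleus: id, centroid_{z,y,x}_um, radius_um, volume_um3,
        dry_mass_pg, dmd_pg_um3, compartment, normalized_radius, fragmented.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    zc, yc, xc = _voxel_coords(config)
    centroids, comps, radii = _place_centroids(config, rng)

    phase = np.zeros((nz, ny, nx), dtype=np.float32)
    channel = np.zeros((nz, ny, nx), dtype=np.float32)
    nucleus_support = np.zeros((nz, ny, nx), dtype=bool)
    voxvol = config.z_step_um / config.lateral_px_per_um**2
    phase_per_density = (
        2.0 * np.pi * config.gamma_um3_per_pg / config.wavelength_um
    )  # φ value giving M = ρ·V under the dry-mass relation
    dmd_max = max(config.dmd_te_pg_per_um3, config.dmd_icm_pg_per_um3)

    rows = []
    for i, (center, comp, r_nuc) in enumerate(zip(centroids, comps, radii)):
        mean_dmd = (
            config.dmd_te_pg_per_um3 if comp == "TE" else config.dmd_icm_pg_per_um3
        )
        dmd = mean_dmd * max(0.5, 1.0 + config.density_rel_sd * rng.normal())
        fragmented = bool(rng.uniform() < config.fragmentation_prob)
        mask = np.zeros((nz, ny, nx), dtype=bool)
        if fragmented:
            # a low-sphericity cluster of 2-4 small overlapping spheres
            n_frag = int(rng.integers(2, 5))
            for _ in range(n_frag):
                frac = rng.uniform(0.40, 0.60) * r_nuc
                off = rng.normal(size=3)
                off = off / np.linalg.norm(off) * rng.uniform(0.3, 0.8) * r_nuc
                _stamp_ellipsoid(mask, zc, yc, xc, center + off, (frac,) * 3, config)
        else:
            lo, hi = config.axis_ratio_range
            semi = r_nuc * rng.uniform(lo, hi, size=3)
            # keep the volume of the nominal sphere
            semi *= r_nuc / np.prod(semi) ** (1.0 / 3.0)
            _stamp_ellipsoid(mask, zc, yc, xc, center, semi, config)

        vox = int(mask.sum())
        if vox == 0:  # pragma: no cover - geometry guarantees nonzero
            raise PlacementError(f"nucleus {i} rasterized to zero voxels")
        phase[mask] = np.float32(phase_per_density * dmd)
        channel[mask] = np.float32(dmd / dmd_max)
        nucleus_support |= mask
        idx = np.argwhere(mask)
        centroid_um = np.array(
            [
                (idx[:, 0].mean() + 0.5) * config.z_step_um,
                (idx[:, 1].mean() + 0.5) / config.lateral_px_per_um,
                (idx[:, 2].mean() + 0.5) / config.lateral_px_per_um,
            ]
        )
        volume_um3 = vox * voxvol
        rows.append(
            dict(
                id=i + 1,
                centroid_z_um=centroid_um[0],
                centroid_y_um=centroid_um[1],
                centroid_x_um=centroid_um[2],
                radius_um=r_nuc,
                volume_um3=volume_um3,
                dry_mass_pg=dmd * volume_um3,
                dmd_pg_um3=dmd,
                compartment=comp,
                fragmented=fragmented,
            )
        )

    truth = pd.DataFrame(rows)
    # normalized radius under the same convention the feature module uses:
    # embryo centre = centroid of nucleus centroids, scale = max distance
    cents = truth[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    d = np.linalg.norm(cents - cents.mean(axis=0), axis=1)
    dmax = d.max()
    truth["normalized_radius"] = d / dmax if dmax > 0 else 0.0

    # smooth cytoplasm blob (parabolic density cap over the embryo ball);
    # the density field is composite — cytoplasm fills the space *between*
    # nuclei, so the phase over a nucleus support integrates to exactly ρ·V
    center = np.array([nz * config.z_step_um / 2.0, ny / config.lateral_px_per_um / 2.0,
                       nx / config.lateral_px_per_um / 2.0])
    dist2 = (
        ((zc - center[0]) ** 2)[:, None, None]
        + ((yc - center[1]) ** 2)[None, :, None]
        + ((xc - center[2]) ** 2)[None, None, :]
    )
    blob = np.clip(1.0 - dist2 / config.embryo_radius_um**2, 0.0, None).astype(
        np.float32
    )
    blob[nucleus_support] = 0.0
    phase += np.float32(config.cyto_density_pg_um3 * phase_per_density) * blob
    channel += np.float32(config.cyto_channel_level) * blob

    if config.noise_sd > 0:
        phase += rng.normal(0.0, config.noise_sd, phase.shape).astype(np.float32)
    if config.nucleus_noise_sd > 0:
        channel += rng.normal(0.0, config.nucleus_noise_sd, channel.shape).astype(
            np.float32
        )

    pv = PhaseVolume(
        phase,
        dx_um=1.0 / config.lateral_px_per_um,
        dz_um=config.z_step_um,
        wavelength_um=config.wavelength_um,
        gamma_um3_per_pg=config.gamma_um3_per_pg,
    )
    return pv, channel, truth


def recovery_benchmark_config(
    n_nuclei: int,
    seed: int,
    lateral_px_per_um: float = 4.0,
    nucleus_noise_sd: float = 0.2,
    **overrides,
) -> SynthConfig:
    """Segmentation-recovery benchmark conditions.

    Spherical (unfragmented) nuclei, surface-to-surface separation above
    2 µm, nucleus-channel SNR of 1/nucleus_noise_sd (default 5); the
    embryo radius grows as n^{1/3} so that cohorts spanning 20–80 nuclei
    stay placeable at constant packing density.
    """
    radius = max(18.0, 8.6 * n_nuclei ** (1.0 / 3.0))
    params = dict(
        embryo_class=EmbryoClass.BLASTOCYST_HEALTHY,
        n_nuclei=n_nuclei,
        embryo_radius_um=radius,
        nucleus_radius_um_range=(2.6, 3.4),
        te_fraction=0.30,
        fragmentation_prob=0.0,
        axis_ratio_range=(1.0, 1.0),
        nucleus_noise_sd=nucleus_noise_sd,
        lateral_px_per_um=lateral_px_per_um,
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def generate_cohort(
    n_embryos: int,
    class_mix: tuple[float, float, float] = (0.30, 0.43, 0.27),
    seed: int = 0,
    **config_overrides,
):
    """Generate a cohort of embryos with a deterministic manifest.

    ``class_mix`` gives the (healthy, intermediate, sick) proportions and
    must sum to 1.  Per-class counts use largest-remainder rounding (floor
    everything, then hand out the remaining embryos in order of decreasing
    fractional part, ties broken by class order).  Per-embryo seeds derive
    from the master ``seed`` via ``numpy.random.SeedSequence``.

    Returns ``(embryos, manifest)`` where ``embryos`` is a list of
    ``(config, phase, nucleus_channel, truth)`` and ``manifest`` a DataFrame
    with embryo_id, embryo_class, label (H/I/S), binary_label (HI/S), seed,
    n_nuclei.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be 3 nonnegative proportions summing to 1")
    raw = mix * n_embryos
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts), kind="stable")
    for j in order[: n_embryos - counts.sum()]:
        counts[j] += 1

    classes = [
        EmbryoClass.BLASTOCYST_HEALTHY,
        EmbryoClass.BLASTOCYST_INTERMEDIATE,
        EmbryoClass.CLEAVAGE_SICK,
    ]
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_embryos)
    ]

    embryos = []
    manifest_rows = []
    k = 0
    for cls, cnt in zip(classes, counts):
        for _ in range(cnt):
            cfg = default_config(cls, seed=child_seeds[k], **config_overrides)
            phase, channel, truth = generate_embryo(cfg)
            embryos.append((cfg, phase, channel, truth))
            manifest_rows.append(
                dict(
                    embryo_id=k,
                    embryo_class=cls.value,
                    label=cls.health_label,
                    binary_label=cls.binary_label,
                    seed=child_seeds[k],
                    n_nuclei=cfg.n_nuclei,
                )
            )
            k += 1
    return embryos, pd.DataFrame(manifest_rows)
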