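"""Linking per-slice 2D labels into 3D nucleus instances.

Stage two of the segmentation: per-slice object centroids are linked into
z-trajectories by greedy nearest-centroid matching, trajectories spanning
two nuclei stacked along z are split at area minima, surviving
trajectories are painted into a 3D label volume, filtered by voxel volume
/ z-depth / extent, and finally resampled to isotropic physical space
(labels nearest-neighbour, phase linear along z).

Default pixel-domain parameters assume the reference calibration of
11 px/µm laterally and a 1 µm z-step; :meth:`Link3DParams.scaled`
rescales them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glim import PhaseVolume
from .seg2d import (
    REFERENCE_PX_PER_UM,
    REFERENCE_Z_STEP_UM,
    Seg2DParams,
    SliceLabelMap,
    segment_stack,
)


@dataclass(frozen=True)
class Link3DParams:
    link_radius_px: float = 50.0
    max_gap_um: float = 5.0
    min_volume_vox: float = 5_000.0
    max_volume_vox: float = 250_000.0
    min_zdepth: int = 3
    min_extent: float = 0.14
    lateral_px_per_um: float = 11.0
    z_step_um: float = 1.0
    #: a candidate split requires the area minimum to fall below this
    #: fraction of the smaller flanking area maximum
    split_area_dip: float = 0.6

    def __post_init__(self):
        for f in ("link_radius_px", "max_gap_um", "min_volume_vox",
                  "max_volume_vox", "min_zdepth", "min_extent",
                  "lateral_px_per_um", "z_step_um"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def scaled(self, lateral_px_per_um: float, z_step_um: float = 1.0) -> "Link3DParams":
        """Rescale voxel-domain parameters to another calibration.

        Lateral lengths scale with ``s = lateral_px_per_um / 11``, voxel
        counts with ``s² · (1 µm / z_step)``, the z-depth with the z-step;
        physical (µm) parameters are unchanged.
        """
        s = lateral_px_per_um / REFERENCE_PX_PER_UM
        t = REFERENCE_Z_STEP_UM / z_step_um
        return replace(
            self,
            link_radius_px=self.link_radius_px * s,
            min_volume_vox=self.min_volume_vox * s * s * t,
            max_volume_vox=self.max_volume_vox * s * s * t,
            min_zdepth=max(2, int(round(self.min_zdepth * t))),
            lateral_px_per_um=lateral_px_per_um,
            z_step_um=z_step_um,
        )


@dataclass
class Trajectory:
    """Ordered per-slice observations of one (candidate) nucleus."""

    zs: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)  # per-slice 2D labels
    centroids: list[tuple[float, float]] = field(default_factory=list)  # (y, x) px
    areas: list[float] = field(default_factory=list)

    def append(self, z: int, label: int, centroid, area: float) -> None:
        self.zs.append(z)
        self.labels.append(label)
        self.centroids.append((float(centroid[0]), float(centroid[1])))
        self.areas.append(float(area))

    @property
    def depth(self) -> int:
        return len(self.zs)

    @property
    def z_span(self) -> tuple[int, int]:
        return self.zs[0], self.zs[-1]


@dataclass
class LabelVolume:
    """3D integer instance-label field plus per-object table and metadata."""

    labels: np.ndarray  # (nz, ny, nx) int32, 0 = background
    voxel_size_um: tuple[float, float, float]  # (dz, dy, dx)
    table: pd.DataFrame  # label, volume_vox, volume_um3, zdepth, extent

    @property
    def n_objects(self) -> int:
        return int(self.table.shape[0])

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx


# ---------------------------------------------------------------------------
# trajectory linking
# ---------------------------------------------------------------------------

def link_trajectories(
    slice_maps: list[SliceLabelMap], params: Link3DParams = Link3DParams()
) -> list[Trajectory]:
    """Greedy nearest-centroid linking of per-slice objects along z.

    At each z-section, open trajectories (those whose last observation is
    within the bridgeable gap) compete for the new objects; pairs are
    assigned in order of increasing centroid distance (ties by lower
    trajectory id), each trajectory and object at most once, and only
    within ``link_radius_px``.  A gap of more than ``max_gap_um`` closes a
    trajectory; unmatched objects start new trajectories.
    """
    if not slice_maps:
        raise ValueError("need at least one slice")
    trajectories: list[Trajectory] = []
    open_idx: list[int] = []

    for z, sl in enumerate(slice_maps):
        # close trajectories whose gap has grown beyond the bridgeable limit
        open_idx = [
            t
            for t in open_idx
            if (z - trajectories[t].zs[-1] - 1) * params.z_step_um <= params.max_gap_um
        ]
        tab = sl.table
        n_obj = len(tab)
        if n_obj:
            obj_cent = tab[["centroid_y", "centroid_x"]].to_numpy()
            obj_labels = tab["label"].to_numpy()
            obj_areas = tab["area"].to_numpy()
            matched_obj = np.zeros(n_obj, dtype=bool)
            matched_traj: set[int] = set()
            if open_idx:
                traj_cent = np.array([trajectories[t].centroids[-1] for t in open_idx])
                dist = np.linalg.norm(
                    traj_cent[:, None, :] - obj_cent[None, :, :], axis=2
                )
                pairs = [
                    (dist[i, j], open_idx[i], j)
                    for i in range(len(open_idx))
                    for j in range(n_obj)
                    if dist[i, j] <= params.link_radius_px
                ]
                pairs.sort(key=lambda p: (p[0], p[1]))
                for d, t, j in pairs:
                    if t in matched_traj or matched_obj[j]:
                        continue
                    trajectories[t].append(z, int(obj_labels[j]), obj_cent[j], obj_areas[j])
                    matched_traj.add(t)
                    matched_obj[j] = True
            for j in np.flatnonzero(~matched_obj):
                traj = Trajectory()
                traj.append(z, int(obj_labels[j]), obj_cent[j], obj_areas[j])
                trajectories.append(traj)
                open_idx.append(len(trajectories) - 1)
    return trajectories


# ---------------------------------------------------------------------------
# splitting stacked nuclei
# ---------------------------------------------------------------------------

def _plateau_minima(a: np.ndarray) -> list[int]:
    """Interior indices of strict (plateau-aware) local minima of ``a``."""
    n = len(a)
    minima = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        if j >= n - 1:
            break
        if a[i - 1] > a[i] and a[j + 1] > a[i]:
            minima.append((i + j) // 2)
        i = j + 1
    return minima


def _has_centroid_evidence(d: np.ndarray, i: int) -> bool:
    """Centroid-transition evidence near index ``i`` of the area minimum.

    The distance-from-first-centroid profile marks a boundary between two
    stacked nuclei either as a local extremum or as a step: when the
    centroid hops from one nucleus to the next, the increment near the
    waist dwarfs the jitter increments elsewhere.  Evidence is a local
    extremum within ±1 slice, or a boundary-window increment larger than
    twice the median increment of the rest of the profile.
    """
    n = len(d)
    for j in (i - 1, i, i + 1):
        if 1 <= j <= n - 2:
            trio = d[j - 1 : j + 2]
            if np.all(np.isfinite(trio)):
                left, mid, right = trio
                if (mid - left) * (right - mid) < 0:
                    return True
    steps = np.abs(np.diff(d))
    steps = np.where(np.isfinite(steps), steps, np.nan)
    window = steps[max(0, i - 1) : i + 2]
    window = window[np.isfinite(window)]
    if window.size == 0:
        return False
    others = np.concatenate([steps[: max(0, i - 1)], steps[i + 2 :]])
    others = others[np.isfinite(others)]
    boundary_jump = float(window.max())
    if others.size == 0:
        return boundary_jump > 0.0
    return boundary_jump > 0.0 and boundary_jump > 2.0 * float(np.median(others))


def split_stacked(
    trajectory: Trajectory, params: Link3DParams = Link3DParams()
) -> list[Trajectory]:
    """Split a trajectory where two nuclei are stacked along z.

    The dense per-z area profile (bridged gaps contribute zero area) is
    scanned for plateau-aware strict local minima whose value falls below
    ``split_area_dip`` times the smaller flanking maximum.  A candidate
    splits the trajectory when the minimum is a bridged gap (zero area —
    the nuclei are physically separated along z) or when the profile of
    centroid distance from the trajectory's first centroid has a local
    extremum within ±1 slice of the minimum.  The boundary falls after the
    minimum slice.  Parts shorter than ``min_zdepth`` are kept and left to
    the downstream z-depth filter — cutting them off here protects a
    genuine nucleus from being dragged below the extent filter by a
    chained stray detection.  Gap-free trajectories shorter than
    ``2·min_zdepth`` are returned unchanged.
    """
    gap_free = trajectory.depth == trajectory.z_span[1] - trajectory.z_span[0] + 1
    if trajectory.depth < 2 * params.min_zdepth and gap_free:
        return [trajectory]
    z0, z1 = trajectory.z_span
    nzd = z1 - z0 + 1
    area = np.zeros(nzd)
    dist = np.full(nzd, np.nan)
    first = np.array(trajectory.centroids[0])
    for z, c, a in zip(trajectory.zs, trajectory.centroids, trajectory.areas):
        area[z - z0] = a
        dist[z - z0] = np.linalg.norm(np.array(c) - first)

    candidates = []
    minima = _plateau_minima(area)
    for i in minima:
        left_max = area[:i].max()
        right_max = area[i + 1 :].max()
        if area[i] >= params.split_area_dip * min(left_max, right_max):
            continue
        if area[i] == 0.0 or _has_centroid_evidence(dist, i):
            candidates.append(i)

    if not candidates:
        return [trajectory]

    zs = np.array(trajectory.zs)
    parts: list[Trajectory] = []
    start = 0  # index into observed entries
    for i in sorted(candidates):
        boundary_z = z0 + i  # minimum slice joins the earlier part
        cut = int(np.searchsorted(zs, boundary_z, side="right"))
        if cut == start or cut == len(zs):
            continue
        parts.append(_subtrajectory(trajectory, start, cut))
        start = cut
    parts.append(_subtrajectory(trajectory, start, len(zs)))
    if len(parts) == 1:
        return [trajectory]
    # recurse: each part may itself contain further stacked nuclei
    out: list[Trajectory] = []
    for p in parts:
        out.extend(split_stacked(p, params) if p.depth < trajectory.depth else [p])
    return out


def _subtrajectory(traj: Trajectory, a: int, b: int) -> Trajectory:
    sub = Trajectory()
    sub.zs = traj.zs[a:b]
    sub.labels = traj.labels[a:b]
    sub.centroids = traj.centroids[a:b]
    sub.areas = traj.areas[a:b]
    return sub


# ---------------------------------------------------------------------------
# assembly, filtering, resampling
# ---------------------------------------------------------------------------

def assemble_and_filter(
    trajectories: list[Trajectory],
    slice_maps: list[SliceLabelMap],
    params: Link3DParams = Link3DParams(),
) -> LabelVolume:
    """Paint trajectories into a 3D label volume and apply the 3D filters.

    Labels are ordered by first z-appearance (ties by first centroid, row
    then column).  Objects outside ``[min_volume_vox, max_volume_vox]``,
    spanning fewer than ``min_zdepth`` sections, or with extent (volume /
    bounding-box volume) below ``min_extent`` are removed; survivors are
    relabelled sequentially preserving the z-order.  Bridged-gap sections
    receive no voxels (they stay background).
    """
    shape = (len(slice_maps),) + slice_maps[0].labels.shape
    order = sorted(
        range(len(trajectories)),
        key=lambda t: (
            trajectories[t].zs[0],
            trajectories[t].centroids[0][0],
            trajectories[t].centroids[0][1],
        ),
    )
    vol = np.zeros(shape, dtype=np.int32)
    rows = []
    voxvol = params.z_step_um / params.lateral_px_per_um**2
    new_id = 0
    for t in order:
        traj = trajectories[t]
        new_id += 1
        voxels = 0
        ys: list[int] = []
        xs: list[int] = []
        for z, lbl in zip(traj.zs, traj.labels):
            m = slice_maps[z].labels == lbl
            vol[z][m] = new_id
            voxels += int(m.sum())
            if m.any():
                yy, xx = np.nonzero(m)
                ys.extend((yy.min(), yy.max()))
                xs.extend((xx.min(), xx.max()))
        zspan = traj.zs[-1] - traj.zs[0] + 1
        bbox = zspan * (max(ys) - min(ys) + 1) * (max(xs) - min(xs) + 1)
        rows.append(
            dict(
                label=new_id,
                volume_vox=voxels,
                volume_um3=voxels * voxvol,
                zdepth=traj.depth,
                extent=voxels / bbox if bbox else 0.0,
            )
        )
    table = pd.DataFrame(rows)
    if len(table):
        ok = (
            (table.volume_vox >= params.min_volume_vox)
            & (table.volume_vox <= params.max_volume_vox)
            & (table.zdepth >= params.min_zdepth)
            & (table.extent >= params.min_extent)
        )
        removed = table.label[~ok].to_numpy()
        if len(removed):
            vol[np.isin(vol, removed)] = 0
        table = table[ok].reset_index(drop=True)
        # relabel sequentially, preserving z-order
        mapping = np.zeros(int(table.label.max()) + 1 if len(table) else 1, dtype=np.int32)
        mapping[table.label.to_numpy()] = np.arange(1, len(table) + 1, dtype=np.int32)
        vol = mapping[vol]
        table = table.assign(label=np.arange(1, len(table) + 1))
    return LabelVolume(
        vol,
        voxel_size_um=(
            params.z_step_um,
            1.0 / params.lateral_px_per_um,
            1.0 / params.lateral_px_per_um,
        ),
        table=table,
    )


def resample_isotropic(
    label_volume: LabelVolume,
    phase: PhaseVolume | None = None,
    params: Link3DParams = Link3DParams(),
) -> tuple[LabelVolume, PhaseVolume | None]:
    """Upsample the z-axis so voxels become cubes of side 1/lateral µm.

    The upsampling factor is ``lateral_px_per_um × z_step_um``; output
    section ``j`` samples the input at position ``(j + 0.5)/f − 0.5``
    (pixel-centre convention, so an ``n``-section input yields
    ``round(n·f)`` sections).  Labels are interpolated nearest-neighbour
    (the label set is preserved), phase linearly along z.  Non-integer
    factors are handled by the same rational resampling, with the rounding
    documented above.
    """
    f = params.lateral_px_per_um * params.z_step_um
    nz = label_volume.labels.shape[0]
    nz_new = int(round(nz * f))
    pos = (np.arange(nz_new) + 0.5) * nz / nz_new - 0.5
    nearest = np.clip(np.round(pos).astype(int), 0, nz - 1)
    labels_iso = label_volume.labels[nearest]
    iso_voxel = 1.0 / params.lateral_px_per_um
    table = label_volume.table.copy()
    if len(table):
        counts = np.bincount(labels_iso.ravel(), minlength=len(table) + 1)
        table = table.assign(
            volume_vox=counts[1:], volume_um3=counts[1:] * iso_voxel**3
        )
    out_labels = LabelVolume(labels_iso, (iso_voxel,) * 3, table)

    phase_iso = None
    if phase is not None:
        i0 = np.clip(np.floor(pos).astype(int), 0, nz - 1)
        i1 = np.clip(i0 + 1, 0, nz - 1)
        w = np.clip(pos - i0, 0.0, 1.0).astype(np.float32)[:, None, None]
        phi = phase.phi
        phase_iso = PhaseVolume(
            phi[i0] * (1 - w) + phi[i1] * w,
            dx_um=phase.dx_um,
            dz_um=iso_voxel,
            wavelength_um=phase.wavelength_um,
            gamma_um3_per_pg=phase.gamma_um3_per_pg,
        )
    return out_labels, phase_iso


def count_map(label_volume: LabelVolume | np.ndarray) -> np.ndarray:
    """Maximum-value z-projection; with z-ordered labels its global maximum
    equals the number of nuclei."""
    labels = (
        label_volume.labels
        if isinstance(label_volume, LabelVolume)
        else np.asarray(label_volume)
    )
    return labels.max(axis=0)


def segment_nucleus_stack(
    stack: np.ndarray,
    seg_params: Seg2DParams = Seg2DParams(),
    link_params: Link3DParams = Link3DParams(),
) -> tuple[LabelVolume, list[Trajectory]]:
    """2D segmentation + trajectory linking + splitting + 3D filtering."""
    slice_maps = segment_stack(stack, seg_params)
    trajectories = link_trajectories(slice_maps, link_params)
    split: list[Trajectory] = []
    for t in trajectories:
        split.extend(split_stacked(t, link_params))
    return assemble_and_filter(split, slice_maps, link_params), split
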