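"""Trajectory linking, stacked-nucleus splitting, 3D filtering, resampling."""

import numpy as np
import pytest
from skimage.draw import disk

from embryoqpi import link3d, seg2d
from embryoqpi.glim import PhaseVolume
from embryoqpi.link3d import Link3DParams, Trajectory


def maps_from_labels(label_images):
    return [
        seg2d.SliceLabelMap(lbl.astype(np.int32), seg2d._object_table(lbl.astype(np.int32)))
        for lbl in label_images
    ]


def disk_stack(centers_by_slice, shape=(300, 300), radius=12):
    """Label images with one disk per (y, x) center per slice."""
    images = []
    for centers in centers_by_slice:
        lbl = np.zeros(shape, dtype=np.int32)
        for i, c in enumerate(centers, start=1):
            rr, cc = disk(c, radius, shape=shape)
            lbl[rr, cc] = i
        images.append(lbl)
    return maps_from_labels(images)


class TestLinkTrajectories:
    def test_two_distant_nuclei_make_two_trajectories(self):
        maps = disk_stack([[(100, 50), (100, 250)]] * 10)
        trajs = link3d.link_trajectories(maps)
        assert len(trajs) == 2
        assert all(t.depth == 10 for t in trajs)

    def test_jittered_centroid_stays_one_trajectory(self, rng):
        centers = [[(150 + int(rng.integers(-10, 11)), 150 + int(rng.integers(-10, 11)))]
                   for _ in range(12)]
        trajs = link3d.link_trajectories(disk_stack(centers))
        assert len(trajs) == 1

    def test_gap_above_limit_starts_new_trajectory(self):
        # object at z=0..4 and z=11..15: the 6 um gap exceeds the 5 um limit
        centers = [[(150, 150)]] * 5 + [[]] * 6 + [[(150, 150)]] * 5
        trajs = link3d.link_trajectories(disk_stack(centers))
        assert len(trajs) == 2

    def test_gap_within_limit_is_bridged(self):
        centers = [[(150, 150)]] * 5 + [[]] * 3 + [[(150, 150)]] * 5
        trajs = link3d.link_trajectories(disk_stack(centers))
        assert len(trajs) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            link3d.link_trajectories([])


def make_trajectory(zs, areas, centroids):
    t = Trajectory()
    for z, a, c in zip(zs, areas, centroids):
        t.append(z, 1, c, a)
    return t


class TestSplitStacked:
    def test_two_stacked_spheres_split_at_central_minimum(self):
        areas = [100, 400, 900, 400, 100, 400, 900, 400, 100]
        # lateral drift gives the distance profile an extremum at the waist
        ys = [0, 0, 0, 0, 3, 6, 6, 6, 6]
        cents = [(y, 0.0) for y in ys]
        parts = link3d.split_stacked(make_trajectory(range(9), areas, cents))
        assert len(parts) == 2
        assert [p.depth for p in parts] == [5, 4]

    def test_monotone_profile_not_split(self):
        areas = [100, 300, 500, 700, 900, 1100]
        cents = [(0.0, 0.0)] * 6
        parts = link3d.split_stacked(make_trajectory(range(6), areas, cents))
        assert len(parts) == 1

    def test_shallow_waist_not_split(self):
        areas = [100, 900, 720, 900, 100, 50, 60]
        ys = [0, 0, 3, 6, 6, 6, 6]
        cents = [(y, 0.0) for y in ys]
        parts = link3d.split_stacked(make_trajectory(range(7), areas, cents))
        assert len(parts) == 1  # dip 720 >= 0.6 * 900

    def test_bridged_gap_between_spheres_splits_without_lateral_offset(self):
        # vertically aligned spheres separated by a bridged 2-slice gap
        zs = [0, 1, 2, 3, 6, 7, 8, 9]
        areas = [200, 500, 500, 200, 200, 500, 500, 200]
        cents = [(0.0, 0.0)] * 8
        parts = link3d.split_stacked(make_trajectory(zs, areas, cents))
        assert len(parts) == 2

    def test_short_trajectory_unchanged(self):
        parts = link3d.split_stacked(
            make_trajectory(range(4), [100, 50, 100, 80], [(0, 0)] * 4)
        )
        assert len(parts) == 1


def sphere_maps(radius_px=15, shape=(80, 80), center=(40, 40), n_z=None):
    n_z = n_z or 2 * radius_px + 1
    images = []
    for z in range(n_z):
        dz = z - (n_z - 1) / 2
        r2 = radius_px**2 - dz**2
        lbl = np.zeros(shape, dtype=np.int32)
        if r2 > 0:
            rr, cc = disk(center, np.sqrt(r2), shape=shape)
            lbl[rr, cc] = 1
        images.append(lbl)
    return maps_from_labels(images)


class TestAssembleAndFilter:
    def test_small_object_removed_by_volume_filter(self):
        # 10 slices x 20x20 square = 4000 voxels < 5000
        lbl = np.zeros((100, 100), dtype=np.int32)
        lbl[40:60, 40:60] = 1
        maps = maps_from_labels([lbl] * 10)
        trajs = link3d.link_trajectories(maps)
        vol = link3d.assemble_and_filter(trajs, maps)
        assert vol.n_objects == 0

    def test_two_plane_object_removed_by_depth_filter(self):
        lbl = np.zeros((120, 120), dtype=np.int32)
        lbl[10:80, 10:80] = 1  # 4900 px2 per plane, 9800 vox total
        maps = maps_from_labels([lbl, lbl, np.zeros_like(lbl)])
        trajs = link3d.link_trajectories(maps)
        assert link3d.assemble_and_filter(trajs, maps).n_objects == 0

    def test_digitized_sphere_survives_all_filters(self):
        maps = sphere_maps(radius_px=15)
        trajs = link3d.link_trajectories(maps)
        vol = link3d.assemble_and_filter(trajs, maps)
        assert vol.n_objects == 1
        # digitization inflates the extent of an r=15 px sphere by ~10%
        assert vol.table.extent.iloc[0] == pytest.approx(np.pi / 6, rel=0.15)

    def test_low_extent_object_removed(self):
        # thin diagonal plate: extent well below 0.14
        images = []
        for z in range(12):
            lbl = np.zeros((200, 400), dtype=np.int32)
            lbl[80:110, 25 * z : 25 * z + 40] = 1
            images.append(lbl)
        maps = maps_from_labels(images)
        trajs = link3d.link_trajectories(maps)
        table_all = link3d.assemble_and_filter(
            trajs, maps, Link3DParams(min_extent=1e-9)
        ).table
        assert (table_all.extent < 0.14).all()
        assert link3d.assemble_and_filter(trajs, maps).n_objects == 0

    def test_labels_ordered_by_first_z(self):
        im0 = np.zeros((200, 200), dtype=np.int32)
        rr, cc = disk((50, 50), 30, shape=im0.shape)
        im0[rr, cc] = 1
        im1 = im0.copy()
        rr, cc = disk((150, 150), 30, shape=im1.shape)
        im1[rr, cc] = 2
        maps = maps_from_labels([im0] + [im1] * 6 + [im1 - (im1 == 1)])
        trajs = link3d.link_trajectories(maps)
        vol = link3d.assemble_and_filter(trajs, maps, Link3DParams(min_volume_vox=100))
        # the object appearing first along z carries the lower label
        first_z = {
            lbl: int(np.nonzero((vol.labels == lbl).any(axis=(1, 2)))[0][0])
            for lbl in vol.table.label
        }
        labels_sorted = sorted(first_z, key=first_z.get)
        assert labels_sorted == sorted(labels_sorted)

    def test_filter_order_independence(self):
        maps = sphere_maps(radius_px=15)
        trajs = link3d.link_trajectories(maps)
        table = link3d.assemble_and_filter(
            trajs, maps, Link3DParams(min_extent=1e-9, min_zdepth=1)
        ).table
        # applying the three filters in any order keeps the same survivors
        base = Link3DParams()
        masks = [
            (table.volume_vox >= base.min_volume_vox) & (table.volume_vox <= base.max_volume_vox),
            table.zdepth >= base.min_zdepth,
            table.extent >= base.min_extent,
        ]
        import itertools
        reference = masks[0] & masks[1] & masks[2]
        for order in itertools.permutations(range(3)):
            combined = np.ones(len(table), dtype=bool)
            for i in order:
                combined &= masks[i]
            assert (combined == reference).all()


class TestResampleIsotropic:
    def test_output_depth_and_label_preservation(self):
        maps = sphere_maps(radius_px=15, n_z=10)
        trajs = link3d.link_trajectories(maps)
        params = Link3DParams(min_volume_vox=1, min_zdepth=1, min_extent=1e-9)
        vol = link3d.assemble_and_filter(trajs, maps, params)
        iso, _ = link3d.resample_isotropic(vol, None, params)
        assert iso.labels.shape[0] == 110  # 10 slices x factor 11
        assert set(np.unique(iso.labels)) == set(np.unique(vol.labels))
        assert iso.voxel_size_um == (1 / 11, 1 / 11, 1 / 11)

    def test_phase_integral_conserved_for_smooth_field(self):
        z = np.linspace(0, np.pi, 12)
        phi = (np.sin(z)[:, None, None] * np.ones((12, 22, 22))).astype(np.float32)
        phase = PhaseVolume(phi, dx_um=1 / 11, dz_um=1.0)
        import pandas as pd

        lbl = link3d.LabelVolume(
            np.zeros(phi.shape, dtype=np.int32), (1.0, 1 / 11, 1 / 11), pd.DataFrame()
        )
        iso_lbl, iso_phase = link3d.resample_isotropic(lbl, phase)
        before = phi.sum() * phase.voxel_volume_um3
        after = iso_phase.phi.sum() * iso_phase.voxel_volume_um3
        assert after == pytest.approx(before, rel=0.01)


class TestCountMap:
    def test_empty_volume_gives_zero_map(self):
        vol = np.zeros((5, 10, 10), dtype=np.int32)
        assert link3d.count_map(vol).max() == 0

    def test_max_projection_counts_nuclei(self):
        vol = np.zeros((6, 30, 30), dtype=np.int32)
        vol[0, 0:5, 0:5] = 1
        vol[2, 10:15, 10:15] = 2
        vol[4, 20:25, 20:25] = 3
        cm = link3d.count_map(vol)
        assert cm.max() == 3
        assert cm.shape == (30, 30)


class TestLinkParams:
    def test_scaling(self):
        p = Link3DParams().scaled(4.0, 1.0)
        assert p.link_radius_px == pytest.approx(50 * 4 / 11)
        assert p.min_volume_vox == pytest.approx(5000 * (4 / 11) ** 2)
        assert p.max_gap_um == 5.0  # physical parameters unchanged
        assert p.min_zdepth == 3

    def test_validation(self):
        with pytest.raises(ValueError):
            Link3DParams(min_extent=0.0)
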