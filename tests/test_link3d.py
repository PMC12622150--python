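"""3D linking: nearest-neighbour assembly vs the brute-force 26-connected
oracle, volume identities, cytoplasm shells, and focus registration."""

import dataclasses
import math

import numpy as np
import pytest

from nucleovol import (
    CytoParams,
    Focus2D,
    LinkParams,
    SegmentationParams,
    VoxelGrid,
    assign_foci,
    cytoplasm_labels,
    cytoplasm_region,
    integrate_object,
    link_foci,
    link_slices,
    nuclei_label_stack,
    segment_nuclei_slice,
)

from phantom_oracles import (
    clean_design,
    clean_suite,
    dapi_threshold,
    exact_config,
    linked_label_stack,
    make_grid,
    oracle_label_stack,
    partitions_equal,
)

_SEG = SegmentationParams(smooth_sigma_px=0, threshold="fixed:0.5",
                          min_area_px2=1, fill_holes=False)


def _slices_from_binary(stack01):
    """LabelSlices from a (z, y, x) binary array."""
    return [
        segment_nuclei_slice(stack01[z].astype(float), _SEG, z=z)
        for z in range(stack01.shape[0])
    ]


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestLinkSlices:
    calib = (0.5, 1.0)  # px, z

    def test_single_nucleus_spanning_slices_2_to_6(self):
        stack = np.zeros((9, 40, 40), dtype=bool)
        for z in range(2, 7):
            stack[z] = _disc((40, 40), 20, 20, 8)
        objs = link_slices(_slices_from_binary(stack), self.calib, LinkParams())
        assert len(objs) == 1
        assert len(objs[0].members) == 5
        assert [z for z, _ in objs[0].members] == [2, 3, 4, 5, 6]

    def test_distance_cap_prevents_merging(self):
        stack = np.zeros((4, 60, 60), dtype=bool)
        for z in range(4):
            stack[z] = _disc((60, 60), 15, 15, 5) | _disc((60, 60), 45, 45, 5)
        objs = link_slices(_slices_from_binary(stack), self.calib,
                          LinkParams(max_link_dist_um=2.0))
        assert len(objs) == 2

    def test_unordered_or_duplicate_z_rejected(self):
        stack = np.zeros((3, 20, 20), dtype=bool)
        stack[:, 8:12, 8:12] = True
        slices = _slices_from_binary(stack)
        with pytest.raises(ValueError, match="ordered"):
            link_slices(slices[::-1], self.calib, LinkParams(min_slices=1))
        slices[1].z = 0
        with pytest.raises(ValueError, match="duplicate|ordered"):
            link_slices(slices, self.calib, LinkParams(min_slices=1))

    def test_gap_bridging_and_monotone_gap_tolerance(self):
        stack = np.zeros((7, 30, 30), dtype=bool)
        for z in (1, 2, 4, 5):  # slice 3 missing
            stack[z] = _disc((30, 30), 15, 15, 6)
        slices = _slices_from_binary(stack)
        n = {
            gap: len(link_slices(slices, self.calib,
                                 LinkParams(max_z_gap=gap, min_slices=1)))
            for gap in (0, 1, 2)
        }
        assert n[0] == 2 and n[1] == 1
        assert n[0] >= n[1] >= n[2]

    def test_min_slices_filter(self):
        stack = np.zeros((5, 30, 30), dtype=bool)
        stack[2] = _disc((30, 30), 15, 15, 6)  # single-slice object
        slices = _slices_from_binary(stack)
        assert len(link_slices(slices, self.calib, LinkParams(min_slices=2))) == 0
        assert len(link_slices(slices, self.calib, LinkParams(min_slices=1))) == 1

    def test_volume_identity_exact(self, small_clean):
        design, grid, _truth, config = small_clean
        _, nuclei, _ = linked_label_stack(grid, config)
        px, dz = grid.calibration
        for obj in nuclei:
            assert obj.volume_um3 == obj.voxel_count * px * px * dz

    def test_oracle_equivalence_on_clean_phantoms(self):
        for design, grid, _truth in clean_suite(8, seed0=300):
            ours, _, _ = linked_label_stack(grid, exact_config(design))
            oracle = oracle_label_stack(grid, dapi_threshold(design))
            assert partitions_equal(ours, oracle)

    def test_partition_invariant_to_label_permutation(self, small_clean):
        design, grid, _truth, config = small_clean
        from nucleovol.segment2d import _records_from_labels
        from phantom_oracles import segment_stack

        slices = segment_stack(grid, config)
        rng = np.random.default_rng(8)
        shuffled = []
        for s in slices:
            k = s.n_components
            perm = np.zeros(k + 1, dtype=np.int32)
            perm[1:] = 1 + rng.permutation(k)
            labels = perm[s.labels]
            shuffled.append(
                type(s)(z=s.z, labels=labels,
                        records=_records_from_labels(labels, labels.astype(float)))
            )
        a = nuclei_label_stack(
            link_slices(slices, grid.calibration, config.link_nuclei), slices
        )
        b = nuclei_label_stack(
            link_slices(shuffled, grid.calibration, config.link_nuclei), shuffled
        )
        assert partitions_equal(a, b)


class TestIntegrateObject:
    def test_constant_channel_mean_is_exact(self, small_clean):
        design, grid, _truth, config = small_clean
        _, nuclei, _ = linked_label_stack(grid, config)
        const = VoxelGrid(
            {"DAPI": grid.channel("DAPI"), "c": np.full(grid.shape, 7.25)},
            *grid.calibration,
        )
        total_img = const.channel("c").sum()
        integrated_sum = 0.0
        for obj in nuclei:
            out = integrate_object(obj, const, "c")
            assert out["mean"] == 7.25
            assert out["integrated"] == 7.25 * obj.voxel_count
            integrated_sum += out["integrated"]
        assert integrated_sum <= total_img  # disjoint objects: subadditive

    def test_noise_free_nuclear_mean_matches_design(self, small_clean):
        design, grid, _truth, config = small_clean
        _, nuclei, _ = linked_label_stack(grid, config)
        spec = design.channel_baselines["DAPI"]
        for obj in nuclei:
            out = integrate_object(obj, grid, "DAPI")
            assert out["mean"] == pytest.approx(
                spec.background + spec.nuclear_amplitude, rel=0.02
            )

    def test_unknown_channel_is_explicit(self, small_clean):
        _design, grid, _truth, config = small_clean
        _, nuclei, _ = linked_label_stack(grid, config)
        with pytest.raises(KeyError, match="unknown channel"):
            integrate_object(nuclei[0], grid, "nope")


class TestCytoplasm:
    def test_shell_volume_matches_analytic_ellipsoid_shell(self):
        # finer axial sampling so voxelization error stays well below the
        # 10 % analytic tolerance
        design = clean_design(seed=52, cells=1, foci=(0, 0),
                              image_shape=(24, 160, 160), z_step=0.5)
        stacks, truth = make_grid(design)
        (_, grid), = stacks.items()
        config = exact_config(design)
        _, nuclei, _ = linked_label_stack(grid, config)
        cell = truth.cells.iloc[0]
        w = 1.5
        shell = cytoplasm_region(nuclei[0], nuclei, CytoParams(shell_width_um=w),
                                 shape=grid.shape, calib=grid.calibration)
        analytic = 4 / 3 * math.pi * (
            (cell.rz_um + w) * (cell.ry_um + w) * (cell.rx_um + w)
            - cell.rz_um * cell.ry_um * cell.rx_um
        )
        assert shell.sum() * grid.voxel_volume_um3 == pytest.approx(analytic, rel=0.10)

    def test_shell_disjoint_from_all_nuclei(self, small_clean):
        design, grid, _truth, config = small_clean
        stack, nuclei, _ = linked_label_stack(grid, config)
        cyto = cytoplasm_labels(stack, grid.calibration, CytoParams())
        assert not np.any((cyto > 0) & (stack > 0))
        assert set(np.unique(cyto)) <= set(np.unique(stack))

    def test_corner_nucleus_is_clipped_safely(self):
        stack = np.zeros((4, 20, 20), dtype=bool)
        stack[0:2, 0:6, 0:6] = True  # touching three image faces
        slices = _slices_from_binary(stack)
        nuclei = link_slices(slices, (0.5, 1.0), LinkParams(min_slices=1,
                                                            border_policy="keep"))
        shell = cytoplasm_region(nuclei[0], nuclei, CytoParams(shell_width_um=1.0),
                                 shape=stack.shape, calib=(0.5, 1.0))
        assert shell.shape == stack.shape
        assert shell.sum() > 0


class TestFoci3D:
    calib = (0.5, 1.0)

    def _focus(self, z, y, x, area=5.0, mean=100.0):
        return Focus2D(z=z, centroid_y=y, centroid_x=x, area_px2=area,
                       mean_intensity=mean, peak_intensity=mean * 1.2,
                       nucleus_label=1)

    def test_single_slice_focus_survives(self):
        foci = link_foci([[self._focus(3, 10, 10)]], self.calib)
        assert len(foci) == 1 and len(foci[0].members) == 1
        assert foci[0].volume_um3 == 5 * 0.5 * 0.5 * 1.0

    def test_adjacent_slices_link_distant_foci_do_not(self):
        per_slice = [
            [self._focus(2, 10, 10), self._focus(2, 30, 30)],
            [self._focus(3, 10.4, 10.2), self._focus(3, 30.2, 29.8)],
        ]
        foci = link_foci(per_slice, self.calib)
        assert len(foci) == 2
        assert all(len(f.members) == 2 for f in foci)
        # two foci in one nucleus farther apart than the cap never merge
        far = link_foci([[self._focus(2, 10, 10)], [self._focus(3, 16, 10)]],
                        self.calib)  # 3 um apart in y
        assert len(far) == 2

    def test_assignment_by_centroid_containment(self, small_clean):
        design, grid, truth, config = small_clean
        from nucleovol import detect_foci_slice
        from phantom_oracles import segment_stack

        slices = segment_stack(grid, config)
        nuclei = link_slices(slices, grid.calibration, config.link_nuclei)
        stack = nuclei_label_stack(nuclei, slices)
        marker = grid.channel(config.foci.channel)
        per_slice = [detect_foci_slice(marker[z], slices[z], config.foci)
                     for z in range(grid.n_z)]
        foci = link_foci(per_slice, grid.calibration, config.link_foci)
        assign_foci(foci, nuclei, label_stack=stack, calib=grid.calibration)
        assert len(foci) == len(truth.foci)
        assert all(f.host_nucleus_id > 0 for f in foci)

    def test_background_focus_left_unassigned(self):
        stack = np.zeros((4, 30, 30), dtype=bool)
        stack[1:3] = _disc((30, 30), 8, 8, 5)
        slices = _slices_from_binary(stack)
        nuclei = link_slices(slices, self.calib, LinkParams(min_slices=1,
                                                            border_policy="keep"))
        label_stack = nuclei_label_stack(nuclei, slices)
        f = link_foci([[self._focus(1, 25, 25)]], self.calib)
        assign_foci(f, nuclei, label_stack=label_stack, calib=self.calib)
        assert f[0].host_nucleus_id == 0

    @pytest.mark.parametrize(
        "kw", [dict(max_link_dist_um=0), dict(max_z_gap=-1), dict(min_slices=0),
               dict(border_policy="maybe")]
    )
    def test_invalid_link_params_rejected(self, kw):
        with pytest.raises(ValueError):
            LinkParams(**kw)
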