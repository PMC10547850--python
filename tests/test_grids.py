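"""Volume container, NIfTI round trips, resampling and rigid mapping."""

import numpy as np
import pytest

from hepajac.grids import (
    Geometry,
    Grid3D,
    LabelGrid,
    RigidTransform,
    apply_rigid,
    box_geometry,
    crop_box_with_margins,
    read_dvf,
    read_volume,
    resample_to,
    write_dvf,
    write_volume,
)
from hepajac.grids import DisplacementField


class TestIO:
    def test_round_trip_preserves_values_and_geometry(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = Grid3D(rng.standard_normal((12, 10, 8)), (1.0, 1.0, 3.0), (5.0, -2.0, 0.0))
        p = tmp_path / "v.nii.gz"
        write_volume(vol, p)
        back = read_volume(p)
        assert isinstance(back, Grid3D)
        np.testing.assert_array_equal(back.values, vol.values)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert np.allclose(back.origin, vol.origin, atol=1e-6)

    def test_label_round_trip_yields_labelgrid(self, tmp_path):
        lab = LabelGrid(np.arange(60, dtype=np.int32).reshape(5, 4, 3) % 6, (2.0, 2.0, 2.0))
        p = tmp_path / "l.nii.gz"
        write_volume(lab, p)
        back = read_volume(p)
        assert isinstance(back, LabelGrid)
        np.testing.assert_array_equal(back.labels, lab.labels)

    def test_dvf_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        dvf = DisplacementField(rng.standard_normal((6, 5, 4, 3)), (2.0, 2.0, 2.5))
        p = tmp_path / "u.nii.gz"
        write_dvf(dvf, p)
        back = read_dvf(p)
        np.testing.assert_allclose(back.u, dvf.u, atol=1e-6)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_zero_volume_keeps_shape(self, tmp_path):
        vol = Grid3D(np.zeros((64, 64, 64)), (1.0, 1.0, 3.0))
        p = tmp_path / "z.nii.gz"
        write_volume(vol, p)
        assert read_volume(p).shape == (64, 64, 64)

    def test_anatomy_round_trip_matches_generator(self, small_anatomy, tmp_path):
        pre_ct, _, _ = small_anatomy
        p = tmp_path / "ct.nii.gz"
        write_volume(pre_ct, p)
        back = read_volume(p)
        assert back.values[10, 10, 10] == pytest.approx(pre_ct.values[10, 10, 10], abs=1e-4)


class TestResample:
    def test_identity_resample(self, ramp_grid):
        out = resample_to(ramp_grid, ramp_grid.geometry)
        np.testing.assert_allclose(out.values, ramp_grid.values, atol=1e-6)

    def test_constant_stays_constant_on_finer_grid(self):
        vol = Grid3D(np.full((10, 10, 10), 7.0), (4.0, 4.0, 4.0))
        fine = Geometry((16, 16, 16), (2.0, 2.0, 2.0), (2.0, 2.0, 2.0))
        out = resample_to(vol, fine)
        assert np.allclose(out.values, 7.0)

    def test_linear_ramp_exact_at_half_spacing(self, ramp_grid):
        # linear interpolation reproduces linear fields exactly inside support
        g = ramp_grid.geometry
        fine = Geometry((35, 16, 12), (1.0, g.spacing[1], g.spacing[2]), g.origin)
        out = resample_to(ramp_grid, fine)
        expect = np.broadcast_to(np.arange(35, dtype=float)[:, None, None], out.shape)
        np.testing.assert_allclose(out.values, expect, atol=1e-6)

    def test_nearest_never_invents_labels(self):
        rng = np.random.default_rng(2)
        lab = LabelGrid(rng.integers(0, 4, (12, 12, 12)).astype(np.int32), (3.0, 3.0, 3.0))
        fine = Geometry((20, 20, 20), (1.7, 1.7, 1.7), (0.3, 0.1, 0.0))
        out = resample_to(lab, fine, "nearest")
        assert set(np.unique(out.labels)) <= set(np.unique(lab.labels))

    def test_label_linear_interp_rejected(self):
        lab = LabelGrid(np.zeros((4, 4, 4), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError):
            resample_to(lab, lab.geometry, "linear")


class TestCropBox:
    def test_single_voxel_with_margins(self):
        m = np.zeros((64, 64, 64), dtype=np.int32)
        m[20, 20, 20] = 1
        box = crop_box_with_margins(LabelGrid(m, (1, 1, 1)), (15, 15, 5))
        assert box.lo == (5, 5, 15)
        assert box.hi == (36, 36, 26)

    def test_clamped_at_volume_edge(self):
        m = np.zeros((30, 30, 30), dtype=np.int32)
        m[0, 29, 5] = 1
        box = crop_box_with_margins(LabelGrid(m, (1, 1, 1)), (10, 10, 10))
        assert box.lo[0] == 0 and box.hi[1] == 30
        assert all(l >= 0 for l in box.lo)

    def test_contains_brute_force_bounding_box(self, small_anatomy):
        _, labels, _ = small_anatomy
        liver = LabelGrid(labels.liver_mask().astype(np.int32), labels.spacing)
        box = crop_box_with_margins(liver, (2, 2, 1))
        nz = np.argwhere(liver.labels)
        lo_bf, hi_bf = nz.min(0), nz.max(0) + 1
        assert all(bl <= l and bh >= h for bl, l, bh, h in zip(box.lo, lo_bf, box.hi, hi_bf))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            crop_box_with_margins(LabelGrid(np.zeros((8, 8, 8), np.int32), (1, 1, 1)), (1, 1, 1))

    def test_box_geometry_spans_box_extent(self):
        m = np.zeros((40, 40, 40), dtype=np.int32)
        m[10:30, 10:30, 10:30] = 1
        box = crop_box_with_margins(LabelGrid(m, (2.0, 2.0, 2.0)), (0, 0, 0))
        geom = box_geometry(box, (10, 10, 10))
        # first and last voxel centers coincide with the box corners
        assert np.allclose(geom.origin, box.geometry.origin)
        last = np.asarray(geom.origin) + 9 * np.asarray(geom.spacing)
        want = np.asarray(box.geometry.origin) + 19 * 2.0
        np.testing.assert_allclose(last, want)


class TestApplyRigid:
    def test_identity_equals_resample(self, ramp_grid):
        out = apply_rigid(ramp_grid, RigidTransform.identity(), ramp_grid.geometry)
        ref = resample_to(ramp_grid, ramp_grid.geometry)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-6)

    def test_translation_moves_impulse_one_voxel(self):
        v = np.zeros((10, 10, 10))
        v[4, 4, 4] = 1.0
        vol = Grid3D(v, (2.0, 2.0, 2.0))
        t = RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = apply_rigid(vol, t, vol.geometry, "nearest")
        assert out.values[5, 4, 4] == 1.0
        assert out.values[4, 4, 4] == 0.0

    def test_90deg_rotation_permutes_bar_axes(self):
        v = np.zeros((21, 21, 21))
        v[6:15, 10, 10] = 1.0  # bar along axis 0
        vol = Grid3D(v, (1.0, 1.0, 1.0), origin=(-10, -10, -10))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = apply_rigid(vol, RigidTransform(rot, np.zeros(3)), vol.geometry, "nearest")
        # out[i,j,k] = v at R^{-1}(world) = v[j, 20-i, k]
        expected = np.transpose(v, (1, 0, 2))[::-1, :, :]
        np.testing.assert_array_equal(out.values, expected)

    def test_rotation_validation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
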