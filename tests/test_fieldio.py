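from __future__ import annotations

import numpy as np
import nibabel as nib
import pytest

from _oracles import trilinear_sample
from locmorph.exceptions import FormatError, ShapeError, ValidationError
from locmorph.fieldio import (
    BrainMask,
    LabelVolume,
    VectorField,
    assemble_cohort,
    bounding_box_diagonal,
    load_label_volume,
    load_mask,
    load_vector_field,
    magnitude_map,
    region_attribution,
    save_label_volume,
    save_mask,
    save_vector_field,
    vector_to_field,
    warp_image,
)


class TestVectorFieldIO:
    def test_round_trip_is_exact(self, tmp_path, rng):
        field = VectorField(data=rng.standard_normal((5, 4, 3, 3)),
                           spacing=(1.5, 2.0, 2.5))
        path = tmp_path / "f.nii.gz"
        save_vector_field(field, path)
        loaded = load_vector_field(path)
        np.testing.assert_array_equal(loaded.data, field.data)
        assert loaded.spacing == field.spacing

    def test_zero_field_round_trip(self, tmp_path):
        field = VectorField(data=np.zeros((8, 8, 8, 3)))
        path = tmp_path / "z.nii.gz"
        save_vector_field(field, path)
        loaded = load_vector_field(path)
        assert loaded.dims == (8, 8, 8)
        assert loaded.data.sum() == 0.0

    def test_4d_and_5d_dialects_equivalent(self, tmp_path, rng):
        data = rng.standard_normal((8, 8, 8, 3))
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(data, aff), tmp_path / "d4.nii.gz")
        nib.save(nib.Nifti1Image(data[:, :, :, np.newaxis, :], aff),
                 tmp_path / "d5.nii.gz")
        f4 = load_vector_field(tmp_path / "d4.nii.gz")
        f5 = load_vector_field(tmp_path / "d5.nii.gz")
        np.testing.assert_array_equal(f4.data, f5.data)

    def test_single_voxel_grid(self, tmp_path):
        field = VectorField(data=np.ones((1, 1, 1, 3)))
        save_vector_field(field, tmp_path / "one.nii.gz")
        loaded = load_vector_field(tmp_path / "one.nii.gz")
        np.testing.assert_array_equal(loaded.data, field.data)

    def test_wrong_component_count_is_format_error(self, tmp_path):
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)),
                 tmp_path / "bad.nii.gz")
        with pytest.raises(FormatError, match=r"\(4, 4, 4, 2\)"):
            load_vector_field(tmp_path / "bad.nii.gz")

    def test_non_finite_values_rejected(self, tmp_path):
        data = np.zeros((3, 3, 3, 3))
        data[0, 0, 0, 0] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "nan.nii.gz")
        with pytest.raises(ValidationError):
            load_vector_field(tmp_path / "nan.nii.gz")

    def test_mask_and_label_round_trip(self, tmp_path, small_mask):
        save_mask(small_mask, tmp_path / "m.nii.gz")
        loaded = load_mask(tmp_path / "m.nii.gz")
        np.testing.assert_array_equal(loaded.voxels, small_mask.voxels)
        atlas = LabelVolume(labels=np.arange(24).reshape(4, 3, 2) % 5,
                            spacing=(1.0, 1.0, 1.0), names={1: "one", 2: "two"})
        save_label_volume(atlas, tmp_path / "a.nii.gz", tmp_path / "a.tsv")
        loaded = load_label_volume(tmp_path / "a.nii.gz", tmp_path / "a.tsv")
        np.testing.assert_array_equal(loaded.labels, atlas.labels)
        assert loaded.names == atlas.names


class TestAssembleCohort:
    def test_p_is_three_times_masked_voxels(self, rng):
        for trial in range(3):
            gen = np.random.default_rng(trial)
            vox = gen.random((4, 5, 6)) < 0.5
            vox[0, 0, 0] = True
            mask = BrainMask(voxels=vox, spacing=(1.0, 1.0, 1.0))
            fields = [VectorField(data=gen.standard_normal(mask.dims + (3,)))
                      for _ in range(3)]
            cohort = assemble_cohort(fields, mask)
            assert cohort.p == 3 * mask.n_voxels

    def test_zero_fields_give_zero_matrix_with_locations(self, small_mask):
        fields = [VectorField(data=np.zeros(small_mask.dims + (3,)),
                              spacing=small_mask.spacing) for _ in range(2)]
        cohort = assemble_cohort(fields, small_mask)
        assert not cohort.X.any()
        assert cohort.locations.shape == (cohort.p, 3)
        # three features of a voxel share one location row
        locs = cohort.locations.reshape(-1, 3, 3)
        assert (locs == locs[:, :1, :]).all()

    def test_permuting_subjects_permutes_rows(self, small_mask, rng):
        fields = [VectorField(data=rng.standard_normal(small_mask.dims + (3,)),
                              spacing=small_mask.spacing) for _ in range(5)]
        ids = [f"s{i}" for i in range(5)]
        perm = [3, 1, 4, 0, 2]
        a = assemble_cohort(fields, small_mask, ids)
        b = assemble_cohort([fields[i] for i in perm], small_mask,
                            [ids[i] for i in perm])
        np.testing.assert_array_equal(b.X, a.X[perm])

    def test_mismatched_field_names_offending_subject(self, small_mask):
        good = VectorField(data=np.zeros(small_mask.dims + (3,)),
                           spacing=small_mask.spacing)
        bad = VectorField(data=np.zeros((9, 9, 9, 3)), spacing=small_mask.spacing)
        with pytest.raises(ShapeError, match="odd_one"):
            assemble_cohort([good, bad], small_mask, ["fine", "odd_one"])

    def test_locations_follow_spacing(self, small_mask, rng):
        fields = [VectorField(data=rng.standard_normal(small_mask.dims + (3,)),
                              spacing=small_mask.spacing) for _ in range(2)]
        cohort = assemble_cohort(fields, small_mask)
        np.testing.assert_allclose(
            cohort.locations[::3],
            cohort.voxel_index * np.asarray(small_mask.spacing),
        )

    def test_vector_to_field_inverts_vectorization(self, small_cohort):
        row = small_cohort.X[0]
        field = vector_to_field(row, small_cohort)
        vox = small_cohort.voxel_index
        np.testing.assert_array_equal(
            field.data[vox[:, 0], vox[:, 1], vox[:, 2], :].ravel(), row
        )
        outside = ~small_cohort.mask.voxels
        assert not field.data[outside].any()


class TestBoundingBoxDiagonal:
    def test_full_cube_closed_form(self):
        mask = BrainMask(voxels=np.ones((10, 10, 10), dtype=bool))
        assert bounding_box_diagonal(mask) == pytest.approx(9 * np.sqrt(3))

    def test_single_voxel_is_zero(self):
        vox = np.zeros((5, 5, 5), dtype=bool)
        vox[2, 3, 1] = True
        assert bounding_box_diagonal(BrainMask(voxels=vox)) == 0.0

    def test_three_four_five(self):
        vox = np.zeros((8, 8, 8), dtype=bool)
        vox[1, 2, 4] = True
        vox[4, 6, 4] = True  # spans 4 x 5 x 1 voxels -> 3-4-0 triangle
        assert bounding_box_diagonal(BrainMask(voxels=vox)) == pytest.approx(5.0)

    def test_invariant_and_monotone(self, rng):
        vox = np.zeros((7, 7, 7), dtype=bool)
        pts = rng.integers(1, 6, size=(5, 3))
        vox[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        base = bounding_box_diagonal(BrainMask(voxels=vox))
        # adding false voxels changes nothing (they were already false)
        assert bounding_box_diagonal(BrainMask(voxels=vox.copy())) == base
        vox2 = vox.copy()
        vox2[0, 0, 0] = True
        assert bounding_box_diagonal(BrainMask(voxels=vox2)) >= base


class TestMagnitudeMap:
    def test_closed_forms_and_oracle(self, rng):
        data = np.zeros((2, 2, 2, 3))
        data[0, 0, 0] = (3.0, 4.0, 0.0)
        assert magnitude_map(VectorField(data=data))[0, 0, 0] == 5.0
        assert not magnitude_map(VectorField(data=np.zeros((3, 3, 3, 3)))).any()
        field = VectorField(data=rng.standard_normal((4, 5, 6, 3)))
        mag = magnitude_map(field)
        for i in range(4):
            for j in range(5):
                for k in range(6):
                    expect = np.sqrt(sum(field.data[i, j, k, a] ** 2 for a in range(3)))
                    assert abs(mag[i, j, k] - expect) < 1e-12

    def test_pointwise_triangle_inequality(self, rng):
        u = rng.standard_normal((4, 4, 4, 3))
        v = rng.standard_normal((4, 4, 4, 3))
        m_sum = magnitude_map(VectorField(data=u + v))
        m_u = magnitude_map(VectorField(data=u))
        m_v = magnitude_map(VectorField(data=v))
        assert (m_sum <= m_u + m_v + 1e-12).all()


class TestRegionAttribution:
    def _atlas(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[:2] = 7
        labels[2:, :2] = 3
        labels[2:, 2:] = 5
        return LabelVolume(labels=labels, names={7: "seven", 3: "three", 5: "five"})

    def test_signal_region_ranks_first(self):
        atlas = self._atlas()
        mag = np.zeros((4, 4, 4))
        mag[atlas.labels == 7] = 2.0
        ranking = region_attribution(mag, atlas, stat="mean")
        assert ranking[0] == ("seven", 2.0)
        assert all(v == 0.0 for _, v in ranking[1:])

    def test_uniform_ties_break_by_label_id(self):
        atlas = self._atlas()
        ranking = region_attribution(np.full((4, 4, 4), 1.5), atlas, stat="mean")
        assert ranking == [("three", 1.5), ("five", 1.5), ("seven", 1.5)]

    def test_mean_matches_masked_average_oracle(self, rng):
        atlas = self._atlas()
        mag = rng.random((4, 4, 4))
        ranking = dict(region_attribution(mag, atlas, stat="mean"))
        for lid, name in atlas.names.items():
            assert abs(ranking[name] - mag[atlas.labels == lid].mean()) < 1e-12

    def test_dims_mismatch_raises(self):
        with pytest.raises(ShapeError):
            region_attribution(np.zeros((3, 3, 3)), self._atlas())


class TestWarpImage:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((5, 6, 7))
        field = VectorField(data=np.zeros((5, 6, 7, 3)))
        np.testing.assert_allclose(warp_image(img, field), img)

    def test_one_voxel_shift_on_ramp(self):
        dims = (8, 4, 4)
        img = np.broadcast_to(np.arange(8, dtype=float)[:, None, None], dims).copy()
        data = np.zeros(dims + (3,))
        data[..., 0] = 2.0  # one voxel at 2 mm spacing
        field = VectorField(data=data, spacing=(2.0, 2.0, 2.0))
        out = warp_image(img, field)
        np.testing.assert_allclose(out[:-1], img[1:])

    def test_matches_per_voxel_trilinear_oracle(self, rng):
        dims = (4, 5, 6)
        img = rng.random(dims)
        field = VectorField(data=0.8 * rng.standard_normal(dims + (3,)),
                            spacing=(1.0, 2.0, 0.5))
        out = warp_image(img, field)
        sp = np.asarray(field.spacing)
        for i in range(dims[0]):
            for j in range(dims[1]):
                for k in range(dims[2]):
                    pos = np.array([i, j, k]) * sp + field.data[i, j, k]
                    expect = trilinear_sample(img, *(pos / sp))
                    assert abs(out[i, j, k] - expect) < 1e-10

    def test_dims_mismatch_raises(self):
        field = VectorField(data=np.zeros((3, 3, 3, 3)))
        with pytest.raises(ShapeError):
            warp_image(np.zeros((4, 4, 4)), field)
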