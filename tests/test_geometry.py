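"""Voxel-index <-> physical-coordinate mapping and its consistency under
cropping, resampling, and NIfTI round trips."""

import numpy as np
import pytest

from geoppe import (
    GeometryError,
    ImageGeometry,
    Volume,
    affine_from_geometry,
    crop_geometry,
    geometry_from_affine,
    load_volume,
    physical_grid,
    physical_to_voxel,
    resample_geometry,
    save_volume,
    voxel_to_physical,
)
from conftest import random_geometry


class TestImageGeometry:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(GeometryError, match="spacing"):
            ImageGeometry(origin=(0, 0, 0), spacing=(1, 0, 1), size=(2, 2, 2))

    def test_rejects_zero_size(self):
        with pytest.raises(GeometryError, match="size"):
            ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(2, 0, 2))

    def test_rejects_non_orthonormal_direction(self):
        bad = np.eye(3)
        bad[0, 1] = 0.1
        with pytest.raises(GeometryError, match="orthonormal"):
            ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(2, 2, 2), direction=bad)

    def test_fov_is_size_times_spacing(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(2, 3, 4), size=(10, 10, 5))
        assert np.allclose(geom.fov, (20, 30, 20))


class TestVoxelToPhysical:
    def test_unit_construction(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(2, 2, 2), size=(4, 4, 4))
        assert np.allclose(voxel_to_physical(geom, (1, 1, 1)), (2, 2, 2))

    def test_origin_is_first_voxel_center(self):
        geom = ImageGeometry(origin=(10, -5, 3), spacing=(1.7, 2.3, 0.9), size=(4, 4, 4))
        assert np.array_equal(voxel_to_physical(geom, (0, 0, 0)), (10, -5, 3))

    def test_flipped_axis(self):
        geom = ImageGeometry(
            origin=(10, 0, 0), spacing=(2, 2, 2), size=(4, 4, 4), direction=np.diag([-1, 1, 1])
        )
        assert np.allclose(voxel_to_physical(geom, (3, 0, 0)), (4, 0, 0))

    def test_out_of_bounds_names_axis(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(4, 4, 4))
        with pytest.raises(GeometryError, match="axis 1"):
            voxel_to_physical(geom, (0, 4, 0))

    def test_matches_homogeneous_affine_oracle(self, rng):
        """Independent oracle: multiply by the 4x4 homogeneous affine."""
        for _ in range(50):
            geom = random_geometry(rng)
            affine = np.eye(4)
            affine[:3, :3] = geom.direction @ np.diag(geom.spacing)
            affine[:3, 3] = geom.origin
            idx = [int(rng.integers(0, s)) for s in geom.size]
            expected = (affine @ np.array([*idx, 1.0]))[:3]
            assert np.allclose(voxel_to_physical(geom, idx), expected, atol=1e-12)

    def test_round_trip_through_inverse(self, rng):
        for _ in range(50):
            geom = random_geometry(rng)
            idx = np.array([int(rng.integers(0, s)) for s in geom.size], dtype=float)
            p = voxel_to_physical(geom, idx)
            assert np.allclose(physical_to_voxel(geom, p), idx, atol=1e-9)


class TestPhysicalGrid:
    def test_unit_cube(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(2, 2, 2))
        grid = physical_grid(geom)
        assert grid.shape == (3, 2, 2, 2)
        assert set(np.unique(grid)) == {0.0, 1.0}

    def test_first_entry_is_origin(self, rng):
        geom = random_geometry(rng)
        assert np.allclose(physical_grid(geom)[:, 0, 0, 0], geom.origin, atol=1e-12)

    def test_equals_per_voxel_loop(self, rng):
        """The vectorized grid must agree with the brute-force loop."""
        for _ in range(10):
            geom = random_geometry(rng, max_size=4)
            grid = physical_grid(geom)
            for i in range(geom.size[0]):
                for j in range(geom.size[1]):
                    for k in range(geom.size[2]):
                        expected = voxel_to_physical(geom, (i, j, k))
                        assert np.allclose(grid[:, i, j, k], expected, atol=1e-10)


class TestCropGeometry:
    def test_origin_moves_to_start_voxel(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(2, 2, 2), size=(8, 8, 8))
        cropped = crop_geometry(geom, (1, 2, 3), (4, 4, 4))
        assert np.allclose(cropped.origin, (2, 4, 6))
        assert cropped.size == (4, 4, 4)
        assert np.array_equal(cropped.spacing, geom.spacing)

    def test_identity_crop(self, rng):
        geom = random_geometry(rng)
        cropped = crop_geometry(geom, (0, 0, 0), geom.size)
        assert cropped == geom

    def test_nested_crops_compose(self, rng):
        for _ in range(20):
            geom = random_geometry(rng, max_size=10)
            size = np.asarray(geom.size)
            a = np.array([int(rng.integers(0, s)) for s in size])
            mid = size - a
            b = np.array([int(rng.integers(0, s)) for s in mid])
            roi = mid - b
            once = crop_geometry(geom, a + b, roi)
            twice = crop_geometry(crop_geometry(geom, a, mid), b, roi)
            assert twice.isclose(once, tol=1e-9)

    def test_out_of_bounds_crop(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(4, 4, 4))
        with pytest.raises(GeometryError, match="exceeds bounds"):
            crop_geometry(geom, (2, 0, 0), (3, 2, 2))

    def test_commutes_with_physical_grid(self, rng):
        for _ in range(10):
            geom = random_geometry(rng, max_size=6)
            size = np.asarray(geom.size)
            start = np.array([int(rng.integers(0, s)) for s in size])
            roi = np.array([int(rng.integers(1, s - st + 1)) for s, st in zip(size, start)])
            sub = physical_grid(crop_geometry(geom, start, roi))
            full = physical_grid(geom)[
                :,
                start[0] : start[0] + roi[0],
                start[1] : start[1] + roi[1],
                start[2] : start[2] + roi[2],
            ]
            assert np.allclose(sub, full, atol=1e-9)


class TestResampleGeometry:
    def test_identity(self, rng):
        geom = random_geometry(rng)
        assert resample_geometry(geom, geom.size).isclose(geom, tol=1e-12)

    def test_halving_doubles_spacing(self):
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), size=(64, 64, 64))
        out = resample_geometry(geom, (32, 64, 64))
        assert np.allclose(out.spacing, (2, 1, 1))

    def test_fov_preserved(self, rng):
        """FOV edges coincide: extent and outer corner both preserved."""
        for _ in range(20):
            geom = random_geometry(rng, max_size=12)
            new_size = [int(rng.integers(1, 13)) for _ in range(3)]
            out = resample_geometry(geom, new_size)
            assert np.allclose(out.fov, geom.fov, atol=1e-9)
            corner_old = geom.origin - geom.direction @ (geom.spacing / 2)
            corner_new = out.origin - out.direction @ (out.spacing / 2)
            assert np.allclose(corner_old, corner_new, atol=1e-9)


class TestNifti:
    def test_affine_round_trip(self, rng, tmp_path):
        geom = random_geometry(rng, max_size=6)
        vol = Volume(rng.normal(size=geom.size), geom)
        save_volume(vol, tmp_path / "x.nii")
        back = load_volume(tmp_path / "x.nii")
        assert back.geometry.isclose(geom, tol=1e-4)
        assert np.allclose(back.data[0], vol.data[0], atol=1e-5)

    def test_multichannel_round_trip(self, rng, tmp_path):
        geom = ImageGeometry(origin=(1, 2, 3), spacing=(1, 1.5, 2), size=(4, 4, 4))
        vol = Volume(rng.normal(size=(2, 4, 4, 4)), geom)
        save_volume(vol, tmp_path / "x.nii")
        back = load_volume(tmp_path / "x.nii")
        assert back.channels == 2
        assert np.allclose(back.data, vol.data, atol=1e-5)

    def test_sheared_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 1] = 0.3  # shear well above tolerance
        with pytest.raises(GeometryError, match="orthogonal"):
            geometry_from_affine(affine, (4, 4, 4))

    def test_affine_from_geometry_inverts_decomposition(self, rng):
        geom = random_geometry(rng)
        back = geometry_from_affine(affine_from_geometry(geom), geom.size)
        assert back.isclose(geom, tol=1e-9)
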