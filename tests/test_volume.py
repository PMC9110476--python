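"""Volume I/O, coordinate normalisation, and oblique-slice extraction."""

import numpy as np
import pytest

from planepose.rotations import Pose, euler_to_rotation
from planepose.volume import (
    SlicePlaneSpec,
    Volume,
    denormalize_translation,
    extract_slice,
    load_slice_png,
    load_volume,
    mm_to_index,
    normalize_translation,
    overlap_fraction,
    save_slice_png,
    save_volume,
    trilinear_sample,
    _volume_points_mm,
)


@pytest.fixture
def random_volume():
    rng = np.random.default_rng(0)
    return Volume(grid=rng.random((32, 32, 32)).astype(np.float32),
                  spacing=np.full(3, 1.0))


def oracle_slice(volume, spec):
    """Naive per-pixel reference: pixel -> mm -> pose transform -> trilinear."""
    n = spec.resolution
    out = np.empty((n, n))
    t_mm = denormalize_translation(spec.pose.translation, volume.extent)
    R = spec.pose.rotation
    grid = np.asarray(volume.grid, dtype=float)
    shape = np.asarray(grid.shape)
    pitch = spec.field_of_view / n
    for i in range(n):
        for j in range(n):
            x = (j + 0.5) * pitch - spec.field_of_view / 2.0
            y = (i + 0.5) * pitch - spec.field_of_view / 2.0
            p = (x * R[:, 0] + y * R[:, 1]) + t_mm
            idx = (p + volume.extent / 2.0) / volume.spacing - 0.5
            if np.any(idx < 0.0) or np.any(idx > shape - 1.0):
                out[i, j] = 0.0
                continue
            b = np.clip(np.floor(idx).astype(int), 0, shape - 2)
            fx, fy, fz = idx - b
            g = grid[b[0]:b[0] + 2, b[1]:b[1] + 2, b[2]:b[2] + 2]
            c00 = g[0, 0, 0] * (1 - fx) + g[1, 0, 0] * fx
            c10 = g[0, 1, 0] * (1 - fx) + g[1, 1, 0] * fx
            c01 = g[0, 0, 1] * (1 - fx) + g[1, 0, 1] * fx
            c11 = g[0, 1, 1] * (1 - fx) + g[1, 1, 1] * fx
            c0 = c00 * (1 - fy) + c10 * fy
            c1 = c01 * (1 - fy) + c11 * fy
            out[i, j] = c0 * (1 - fz) + c1 * fz
    return out


class TestVolumeIO:
    def test_round_trip_exact(self, tmp_path, random_volume):
        path = tmp_path / "vol.nii.gz"
        save_volume(random_volume, path)
        back = load_volume(path)
        np.testing.assert_array_equal(back.grid, random_volume.grid)
        np.testing.assert_allclose(back.spacing, random_volume.spacing)

    def test_half_mm_isotropic_spacing_preserved(self, tmp_path):
        vol = Volume(grid=np.zeros((8, 8, 8), dtype=np.float32),
                     spacing=np.full(3, 0.5))
        path = tmp_path / "vol.nii.gz"
        save_volume(vol, path)
        np.testing.assert_allclose(load_volume(path).spacing, (0.5, 0.5, 0.5))

    def test_4d_file_rejected_with_dimensionality(self, tmp_path):
        import nibabel as nib
        path = tmp_path / "vol4d.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32),
                                 np.eye(4)), str(path))
        with pytest.raises(ValueError, match="4 dim"):
            load_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii.gz")

    def test_out_of_range_intensities_rescaled(self, tmp_path):
        import nibabel as nib
        data = np.linspace(-100, 400, 64, dtype=np.float32).reshape(4, 4, 4)
        path = tmp_path / "raw.nii.gz"
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
        vol = load_volume(path)
        assert vol.grid.min() == pytest.approx(0.0)
        assert vol.grid.max() == pytest.approx(1.0)

    def test_non_isotropic_warns_but_loads(self, tmp_path, caplog):
        vol = Volume(grid=np.zeros((4, 4, 4), dtype=np.float32),
                     spacing=(1.0, 1.0, 2.0))
        path = tmp_path / "aniso.nii.gz"
        save_volume(vol, path)
        np.testing.assert_allclose(load_volume(path).spacing, (1, 1, 2))

    def test_invalid_grid_or_spacing(self):
        with pytest.raises(ValueError):
            Volume(grid=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            Volume(grid=np.zeros((4, 4, 4)), spacing=(1, 0, 1))


class TestTranslationNormalisation:
    def test_zero_and_half_extent(self):
        extent = np.array([249.0, 199.0, 160.0])
        np.testing.assert_array_equal(normalize_translation((0, 0, 0), extent),
                                      (0, 0, 0))
        t = normalize_translation((124.5, 0, 0), extent)
        assert t[0] == pytest.approx(1.0)

    def test_denormalize_examples(self):
        extent = np.array([200.0, 200.0, 200.0])
        np.testing.assert_allclose(denormalize_translation((1, 0, 0), extent),
                                   (100, 0, 0))

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        extent = np.array([249.0, 199.0, 160.0])
        t = rng.uniform(-1, 1, 3)
        np.testing.assert_allclose(
            normalize_translation(denormalize_translation(t, extent), extent),
            t, atol=1e-12)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError):
            normalize_translation((1, 1, 1), (0, 1, 1))


class TestExtractSlice:
    def test_constant_volume_any_pose(self):
        vol = Volume(grid=np.full((16, 16, 16), 0.7), spacing=np.ones(3))
        pose = Pose(euler_to_rotation((30, 20, 10)), np.zeros(3))
        sl = extract_slice(vol, SlicePlaneSpec(pose, field_of_view=6.0,
                                               resolution=16))
        np.testing.assert_allclose(sl.pixels, 0.7, atol=1e-12)
        assert sl.overlap == 1.0

    def test_far_outside_all_fill(self, random_volume):
        pose = Pose(np.eye(3), np.array([5.0, 0.0, 0.0]))  # 5 half-extents away
        sl = extract_slice(random_volume,
                           SlicePlaneSpec(pose, field_of_view=10.0, resolution=8))
        np.testing.assert_array_equal(sl.pixels, 0.0)
        assert sl.overlap == 0.0

    def test_matches_per_pixel_oracle_bitwise(self, random_volume):
        rng = np.random.default_rng(2)
        from planepose.rotations import random_rotation
        for _ in range(10):
            pose = Pose(random_rotation(rng), rng.uniform(-0.4, 0.4, 3))
            spec = SlicePlaneSpec(pose, field_of_view=24.0, resolution=24)
            got = extract_slice(random_volume, spec).pixels
            np.testing.assert_array_equal(got, oracle_slice(random_volume, spec))

    def test_matches_map_coordinates(self, random_volume):
        # independent library oracle (different interpolation code path)
        from scipy.ndimage import map_coordinates
        rng = np.random.default_rng(3)
        from planepose.rotations import random_rotation
        pose = Pose(random_rotation(rng), rng.uniform(-0.2, 0.2, 3))
        spec = SlicePlaneSpec(pose, field_of_view=16.0, resolution=20)
        pts = _volume_points_mm(spec, random_volume.extent)
        idx = mm_to_index(pts, random_volume)
        ref = map_coordinates(np.asarray(random_volume.grid, float), idx.T,
                              order=1, mode="constant", cval=0.0)
        got = extract_slice(random_volume, spec).pixels.ravel()
        inside = np.all((idx >= 0) & (idx <= 31), axis=1)
        np.testing.assert_allclose(got[inside], ref[inside], atol=1e-12)

    def test_embedded_pattern_recovered(self):
        # Build a volume by smearing a known 2D pattern along z, slice at
        # the identity pose, and require near-perfect correlation.
        rng = np.random.default_rng(4)
        pattern = rng.random((32, 32))
        grid = np.repeat(pattern[:, :, None], 32, axis=2).transpose(1, 0, 2)
        vol = Volume(grid=grid, spacing=np.ones(3))
        spec = SlicePlaneSpec(Pose(), field_of_view=32.0, resolution=32)
        sl = extract_slice(vol, spec).pixels
        inner = np.s_[4:-4, 4:-4]
        corr = np.corrcoef(sl[inner].ravel(), pattern[inner].ravel())[0, 1]
        assert corr > 0.99


class TestOverlapFraction:
    def test_centered_small_plane_full_overlap(self, random_volume):
        spec = SlicePlaneSpec(Pose(), field_of_view=16.0, resolution=16)
        assert overlap_fraction(random_volume, spec) == 1.0

    def test_fully_outside_zero(self, random_volume):
        pose = Pose(np.eye(3), np.array([0.0, 0.0, 4.0]))
        spec = SlicePlaneSpec(pose, field_of_view=16.0, resolution=16)
        assert overlap_fraction(random_volume, spec) == 0.0

    def test_face_centred_plane_about_half(self, random_volume):
        # plane centre on the +x volume face, plane normal along z: half of
        # the in-plane x-axis extends outside (up to grid quantisation)
        pose = Pose(np.eye(3), np.array([1.0, 0.0, 0.0]))
        spec = SlicePlaneSpec(pose, field_of_view=16.0, resolution=64)
        frac = overlap_fraction(random_volume, spec)
        assert frac == pytest.approx(0.5, abs=0.06)

    def test_monotone_along_outward_normal(self, random_volume):
        fracs = []
        for tx in np.linspace(0.0, 1.5, 7):
            pose = Pose(np.eye(3), np.array([tx, 0.0, 0.0]))
            spec = SlicePlaneSpec(pose, field_of_view=24.0, resolution=24)
            fracs.append(overlap_fraction(random_volume, spec))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestPng:
    def test_round_trip_within_quantisation(self, tmp_path):
        rng = np.random.default_rng(5)
        img = rng.random((16, 16))
        path = tmp_path / "s.png"
        save_slice_png(img, path)
        back = load_slice_png(path)
        assert np.abs(back - img).max() <= 0.5 / 255.0 + 1e-12

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SlicePlaneSpec(Pose(), field_of_view=0.0, resolution=16)
        with pytest.raises(ValueError):
            SlicePlaneSpec(Pose(), field_of_view=10.0, resolution=1)
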