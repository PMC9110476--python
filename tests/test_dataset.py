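"""Pose sampling, manifest round-trips, and dataset construction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from planepose.dataset import (
    DatasetManifest,
    PoseSamplerConfig,
    build_dataset,
    read_manifest,
    sample_near_sp_poses,
    sample_random_pose,
    write_manifest,
)
from planepose.phantom import (
    PhantomParams,
    canonical_standard_plane,
    generate_phantom_volume,
)
from planepose.rotations import geodesic_distance_deg
from planepose.volume import (
    SlicePlaneSpec,
    extract_slice,
    load_slice_png,
    overlap_fraction,
)


@pytest.fixture(scope="module")
def volume():
    return generate_phantom_volume(PhantomParams.for_shape((40, 40, 40), 1.0, seed=3))


@pytest.fixture(scope="module")
def sp():
    return canonical_standard_plane()


class TestRandomPoseSampling:
    def test_degenerate_ranges_give_centred_identity(self, volume):
        cfg = PoseSamplerConfig(trans_range=0.0, rot_range=0.0)
        pose = sample_random_pose(np.random.default_rng(0), cfg, volume)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-15)
        np.testing.assert_array_equal(pose.translation, np.zeros(3))

    def test_seeded_sequence_reproducible(self, volume):
        cfg = PoseSamplerConfig()
        seq1 = [sample_random_pose(np.random.default_rng(1), cfg, volume)
                for _ in range(1)]
        seq2 = [sample_random_pose(np.random.default_rng(1), cfg, volume)
                for _ in range(1)]
        np.testing.assert_array_equal(seq1[0].rotation, seq2[0].rotation)
        np.testing.assert_array_equal(seq1[0].translation, seq2[0].translation)

    def test_emitted_poses_respect_min_overlap(self, volume):
        cfg = PoseSamplerConfig(min_overlap=0.75)
        rng = np.random.default_rng(2)
        fov = float(volume.extent.min())
        for _ in range(200):
            pose = sample_random_pose(rng, cfg, volume, fov)
            spec = SlicePlaneSpec(pose, field_of_view=fov, resolution=24)
            assert overlap_fraction(volume, spec) >= 0.75

    def test_impossible_overlap_raises_with_advice(self, volume):
        cfg = PoseSamplerConfig(trans_range=0.5, min_overlap=0.999999)
        with pytest.raises(RuntimeError, match="min_overlap"):
            sample_random_pose(np.random.default_rng(3), cfg, volume)


class TestNearSpSampling:
    def test_zero_intervals_reproduce_sp(self, volume, sp):
        cfg = PoseSamplerConfig(n_near_sp=5, sp_trans_interval_max=0.0,
                                sp_trans_interval_min=0.0,
                                sp_rot_interval_max=0.0, sp_rot_interval_min=0.0)
        poses = sample_near_sp_poses(np.random.default_rng(4), sp, cfg, volume)
        assert len(poses) == 5
        for pose in poses:
            # arccos near zero angle is accurate only to ~1e-6 deg
            assert geodesic_distance_deg(pose.rotation, sp.pose.rotation) < 1e-5
            np.testing.assert_array_equal(pose.translation, sp.pose.translation)

    def test_default_intervals_bound_perturbations(self, volume, sp):
        cfg = PoseSamplerConfig(n_near_sp=50)
        poses = sample_near_sp_poses(np.random.default_rng(5), sp, cfg, volume)
        for pose in poses:
            dt = np.linalg.norm(pose.translation - sp.pose.translation)
            assert dt <= 0.1 * np.sqrt(3) + 1e-12
            dr = geodesic_distance_deg(pose.rotation, sp.pose.rotation)
            assert dr <= 3 * 7.9 + 1e-9

    def test_interval_ramp_decreases(self, volume, sp):
        cfg = PoseSamplerConfig(n_near_sp=40, min_overlap=0.0)
        poses = sample_near_sp_poses(np.random.default_rng(6), sp, cfg, volume)
        dt = [np.linalg.norm(p.translation - sp.pose.translation) for p in poses]
        assert np.mean(dt[:10]) > np.mean(dt[-10:])

    def test_seeded_reproducible(self, volume, sp):
        cfg = PoseSamplerConfig(n_near_sp=3)
        p1 = sample_near_sp_poses(np.random.default_rng(7), sp, cfg, volume)
        p2 = sample_near_sp_poses(np.random.default_rng(7), sp, cfg, volume)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.rotation, b.rotation)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PoseSamplerConfig(sp_trans_interval_max=0.001, sp_trans_interval_min=0.1)
        with pytest.raises(ValueError):
            PoseSamplerConfig(min_overlap=1.5)
        with pytest.raises(ValueError):
            PoseSamplerConfig(n_random=-1)


class TestManifestIO:
    def _tiny_manifest(self):
        rows = pd.DataFrame([
            {"image_path": "images/rp_000000.png", "volume_id": "v", "subset": "RP",
             "t_x": 0.123456789012345, "t_y": -0.2, "t_z": 0.0,
             "a_x": 10.0, "a_y": -20.0, "a_z": 30.000000000001, "overlap": 1.0},
            {"image_path": "images/sp_000001.png", "volume_id": "v", "subset": "SP",
             "t_x": 0.0, "t_y": 0.04, "t_z": 0.06,
             "a_x": 12.0, "a_y": 0.0, "a_z": 7.0, "overlap": 0.98},
        ])
        meta = {"euler_convention": "ZXY", "field_of_view": 40.0,
                "resolution": 32, "seed": 0}
        return DatasetManifest(rows=rows, meta=meta)

    def test_round_trip_lossless(self, tmp_path):
        manifest = self._tiny_manifest()
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        back = read_manifest(path)
        pd.testing.assert_frame_equal(back.rows, manifest.rows)
        assert back.meta["euler_convention"] == "ZXY"
        assert back.meta["field_of_view"] == 40.0
        assert back.meta["resolution"] == 32

    def test_missing_convention_header_rejected(self, tmp_path):
        manifest = self._tiny_manifest()
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        text = "\n".join(line for line in path.read_text().splitlines()
                         if not line.startswith("# euler_convention"))
        path.write_text(text + "\n")
        with pytest.raises(ValueError, match="euler_convention"):
            read_manifest(path)

    def test_unknown_subset_rejected(self):
        manifest = self._tiny_manifest()
        rows = manifest.rows.copy()
        rows.loc[1, "subset"] = "XX"
        with pytest.raises(ValueError, match="row 1"):
            DatasetManifest(rows=rows, meta=manifest.meta)

    def test_non_finite_values_rejected(self):
        manifest = self._tiny_manifest()
        rows = manifest.rows.copy()
        rows.loc[0, "t_x"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            DatasetManifest(rows=rows, meta=manifest.meta)

    def test_missing_column_rejected(self):
        manifest = self._tiny_manifest()
        with pytest.raises(ValueError, match="overlap"):
            DatasetManifest(rows=manifest.rows.drop(columns=["overlap"]),
                            meta=manifest.meta)


class TestBuildDataset:
    def test_counts_poses_and_pngs(self, tmp_path, volume, sp):
        cfg = PoseSamplerConfig(n_random=12, n_near_sp=4, seed=8)
        manifest = build_dataset(volume, sp, cfg, tmp_path, resolution=24)
        assert (manifest.rows["subset"] == "RP").sum() == 12
        assert (manifest.rows["subset"] == "SP").sum() == 4
        for rel in manifest.rows["image_path"]:
            img = load_slice_png(tmp_path / rel)
            assert img.shape == (24, 24)
        # poses valid + manifest written
        back = read_manifest(tmp_path / "manifest.csv")
        assert len(back.rows) == 16

    def test_reslicing_reproduces_pngs(self, tmp_path, volume, sp):
        cfg = PoseSamplerConfig(n_random=6, n_near_sp=2, seed=9)
        manifest = build_dataset(volume, sp, cfg, tmp_path, resolution=24)
        fov = manifest.meta["field_of_view"]
        for i, rel in enumerate(manifest.rows["image_path"]):
            stored = load_slice_png(tmp_path / rel)
            spec = SlicePlaneSpec(manifest.pose(i), field_of_view=fov,
                                  resolution=24)
            fresh = extract_slice(volume, spec).pixels
            assert np.abs(stored - fresh).max() <= 1.0 / 255.0

    def test_same_seed_identical_manifest(self, tmp_path, volume, sp):
        cfg = PoseSamplerConfig(n_random=5, n_near_sp=2, seed=10)
        m1 = build_dataset(volume, sp, cfg, tmp_path / "a", resolution=16)
        m2 = build_dataset(volume, sp, cfg, tmp_path / "b", resolution=16)
        pd.testing.assert_frame_equal(m1.rows, m2.rows)
        assert ((tmp_path / "a" / "manifest.csv").read_text()
                == (tmp_path / "b" / "manifest.csv").read_text())

    def test_sp_required_when_requested(self, tmp_path, volume):
        cfg = PoseSamplerConfig(n_random=1, n_near_sp=1)
        with pytest.raises(ValueError, match="annotation"):
            build_dataset(volume, None, cfg, tmp_path)

    def test_sp_subset_is_nearer_than_rp(self, tmp_path, volume, sp):
        cfg = PoseSamplerConfig(n_random=30, n_near_sp=30, seed=11)
        manifest = build_dataset(volume, sp, cfg, tmp_path, resolution=16)
        dist = np.array([
            geodesic_distance_deg(manifest.pose(i).rotation, sp.pose.rotation)
            for i in range(len(manifest.rows))])
        is_sp = (manifest.rows["subset"] == "SP").to_numpy()
        assert np.median(dist[is_sp]) < np.median(dist[~is_sp])
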