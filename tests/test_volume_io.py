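import numpy as np
import pytest

from vasctda import (
    LabelVolume,
    PointCloud3D,
    VolumeStack,
    attach_region_labels,
    read_point_cloud,
    read_volume,
    subsample,
    threshold_to_points,
    volume_metric,
    write_point_cloud,
    write_volume,
)


class TestReadWriteVolume:
    def test_tiff_stack_identity(self, tmp_path):
        import tifffile

        path = tmp_path / "zeros.tif"
        tifffile.imwrite(path, np.zeros((4, 2, 2), dtype=np.float32))
        vol = read_volume(path, spacing=(1, 1, 1))
        assert vol.shape == (4, 2, 2)
        assert vol.values.min() == vol.values.max() == 0

    def test_hdf5_uniform(self, tmp_path):
        import h5py

        path = tmp_path / "prob.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("exported_data", data=np.full((10, 10, 10), 0.7))
        vol = read_volume(path, dataset="exported_data", spacing=(1, 1, 1))
        assert vol.values.min() == vol.values.max() == pytest.approx(0.7)

    @pytest.mark.parametrize("name", ["round.h5", "round.tif"])
    def test_round_trip_value_identical(self, tmp_path, rng, name):
        values = rng.uniform(size=(3, 4, 5)).astype(np.float32)
        vol = VolumeStack(values, (2.0, 2.0, 10.0))
        path = tmp_path / name
        write_volume(vol, path)
        back = read_volume(path, spacing=vol.spacing)
        np.testing.assert_array_equal(back.values, values)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_volume("does/not/exist.h5")

    def test_default_spacing_warns(self, tmp_path, caplog):
        import tifffile

        path = tmp_path / "v.tif"
        tifffile.imwrite(path, np.zeros((2, 2, 2), dtype=np.float32))
        with caplog.at_level("WARNING"):
            vol = read_volume(path)
        assert vol.spacing == (1.0, 1.0, 1.0)
        assert any("spacing" in r.message for r in caplog.records)


class TestThresholdToPoints:
    def test_counts_above_cutoff(self):
        values = np.full((2, 2, 2), 0.1)
        values[0, 0, 0] = values[0, 1, 1] = values[1, 0, 1] = 0.9
        cloud = threshold_to_points(VolumeStack(values), 0.5)
        assert cloud.n == 3

    @pytest.mark.parametrize(
        "threshold,expected", [(0.0, 8), (0.5, 1000), (0.9, 0)]
    )
    def test_threshold_extremes(self, threshold, expected):
        if expected == 8:
            vol = VolumeStack(np.abs(np.arange(8)).reshape(2, 2, 2).astype(float))
        else:
            vol = VolumeStack(np.full((10, 10, 10), 0.7))
        assert threshold_to_points(vol, threshold).n == expected

    def test_monotone_in_threshold(self, rng):
        vol = VolumeStack(rng.uniform(size=(6, 6, 6)))
        lo = threshold_to_points(vol, 0.3)
        hi = threshold_to_points(vol, 0.7)
        lo_set = {tuple(p) for p in lo.coords}
        assert all(tuple(p) in lo_set for p in hi.coords)

    def test_voxel_center_coordinates(self):
        values = np.zeros((2, 2, 2))
        values[1, 0, 1] = 1.0  # iz=1, iy=0, ix=1
        cloud = threshold_to_points(VolumeStack(values, (6.45, 6.45, 10.0)), 0.5)
        np.testing.assert_allclose(cloud.coords[0], [1.5 * 6.45, 0.5 * 6.45, 1.5 * 10.0])

    def test_index_roundtrip_through_spacing(self, rng):
        spacing = (6.45, 6.45, 10.0)
        vol = VolumeStack(rng.uniform(size=(4, 5, 6)), spacing)
        cloud = threshold_to_points(vol, 0.0)
        idx = np.floor(cloud.coords / np.array(spacing)).astype(int)
        assert idx[:, 0].max() == 5 and idx[:, 1].max() == 4 and idx[:, 2].max() == 3


class TestRegionLabels:
    def test_uniform_label(self):
        cloud = PointCloud3D([[1.5, 1.5, 1.5]])
        labels = LabelVolume(np.full((3, 3, 3), 7, dtype=int))
        out = attach_region_labels(cloud, labels, (1, 1, 1))
        assert out.region_id.tolist() == [7]

    def test_split_grid(self):
        grid = np.zeros((2, 2, 4), dtype=int)
        grid[:, :, :2] = 3
        grid[:, :, 2:] = 5
        cloud = PointCloud3D([[0.5, 0.5, 0.5], [3.5, 0.5, 0.5]])
        out = attach_region_labels(cloud, LabelVolume(grid), (1, 1, 1))
        assert out.region_id.tolist() == [3, 5]

    def test_out_of_bounds_names_point(self):
        cloud = PointCloud3D([[0.5, 0.5, 0.5], [9.0, 0.5, 0.5]])
        labels = LabelVolume(np.ones((2, 2, 2), dtype=int))
        with pytest.raises(IndexError, match="point 1"):
            attach_region_labels(cloud, labels, (1, 1, 1))


class TestVolumeMetric:
    @pytest.mark.parametrize(
        "n,spacing,expected",
        [
            (100, (10, 10, 10), 1.0e5),
            (0, (10, 10, 10), 0.0),
            (3, (6.45, 6.45, 10.0), 3 * 6.45 * 6.45 * 10.0),
        ],
    )
    def test_count_times_voxel_volume(self, n, spacing, expected):
        cloud = PointCloud3D(np.random.default_rng(0).uniform(size=(n, 3)))
        count, vol = volume_metric(cloud, spacing)
        assert count == n
        assert vol == pytest.approx(expected)

    def test_additive_over_disjoint_clouds(self, rng):
        a = PointCloud3D(rng.uniform(0, 1, (40, 3)))
        b = PointCloud3D(rng.uniform(10, 11, (60, 3)))
        merged = PointCloud3D(np.vstack([a.coords, b.coords]))
        spacing = (2.0, 2.0, 2.0)
        assert (
            volume_metric(merged, spacing)[1]
            == pytest.approx(volume_metric(a, spacing)[1] + volume_metric(b, spacing)[1])
        )


class TestSubsample:
    def test_noop_when_small(self, rng):
        cloud = PointCloud3D(rng.uniform(size=(10, 3)))
        assert subsample(cloud, 10, seed=0) is cloud

    def test_deterministic_and_subset(self, rng):
        cloud = PointCloud3D(rng.uniform(size=(1000, 3)))
        s1 = subsample(cloud, 100, seed=7)
        s2 = subsample(cloud, 100, seed=7)
        np.testing.assert_array_equal(s1.coords, s2.coords)
        assert s1.n == 100
        full = {tuple(p) for p in cloud.coords}
        assert all(tuple(p) in full for p in s1.coords)


class TestPointCloudCSV:
    def test_round_trip(self, tmp_path, rng):
        cloud = PointCloud3D(
            rng.uniform(size=(20, 3)), rng.integers(0, 5, 20), channel="Prox1"
        )
        path = tmp_path / "cloud.csv"
        write_point_cloud(cloud, path)
        header = path.read_text().splitlines()[0]
        assert header == "x_um,y_um,z_um,region_id,channel"
        back = read_point_cloud(path)
        np.testing.assert_allclose(back.coords, cloud.coords)
        np.testing.assert_array_equal(back.region_id, cloud.region_id)
        assert back.channel == "Prox1"


class TestInvariants:
    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            VolumeStack(np.zeros((2, 2, 2)), (1, 0, 1))

    def test_non_finite_rejected(self):
        values = np.zeros((2, 2, 2))
        values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VolumeStack(values)

    def test_region_id_length_checked(self):
        with pytest.raises(ValueError):
            PointCloud3D(np.zeros((3, 3)), region_id=[1, 2])
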