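"""Stage-2 nucleus segmentation: cropping, normalization, watershed backend, features."""

import numpy as np
import pytest

from organoid3d.nuclei_segmentation import (
    BackendConfig,
    crop_organoid,
    normalize_percentile,
    nucleus_features,
    segment_nuclei,
)
from organoid3d.organoid_segmentation import LabeledVolume
from organoid3d.plate_io import PlateLayout, WellVolume


def _well(data, voxel=(1.0, 1.0, 1.0), channels=None):
    c, nz, ny, nx = data.shape
    channels = channels or tuple(f"c{i}" for i in range(c))
    layout = PlateLayout(rows=1, cols=1, field_grid=(1, 1), planes_per_field=nz,
                         channels=channels, field_shape_px=(ny, nx),
                         voxel_size_um=voxel)
    return WellVolume(data, layout)


class TestCropOrganoid:
    def test_zero_pad_crop_shape(self, rng):
        vol = _well(rng.integers(0, 99, (2, 4, 6, 8), dtype=np.uint16))
        crop, offset = crop_organoid(vol, (0, 0, 0, 2, 3, 4), pad_voxels=0)
        assert crop.shape == (2, 2, 3, 4)
        assert offset == (0, 0, 0)
        np.testing.assert_array_equal(crop, vol.data[:, 0:2, 0:3, 0:4])

    def test_pad_clipped_at_volume_edge(self, rng):
        vol = _well(rng.integers(0, 99, (1, 4, 6, 8), dtype=np.uint16))
        crop, offset = crop_organoid(vol, (1, 1, 1, 3, 5, 7), pad_voxels=5)
        assert crop.shape == (1, 4, 6, 8)  # clipped to the whole volume
        assert offset == (0, 0, 0)

    def test_empty_bbox_rejected(self, rng):
        vol = _well(rng.integers(0, 99, (1, 4, 6, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="empty bbox"):
            crop_organoid(vol, (2, 0, 0, 2, 3, 4))


class TestNormalizePercentile:
    def test_full_range_linear_map(self):
        x = np.arange(101, dtype=float).reshape(1, 1, 101)
        out = normalize_percentile(x, 0, 100)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_allclose(out.ravel(), x.ravel() / 100.0)

    def test_constant_crop_returns_zeros(self):
        out = normalize_percentile(np.full((3, 4, 5), 9.0), 1, 99.8)
        assert (out == 0).all()

    def test_matches_direct_formula_oracle(self, rng):
        x = rng.normal(100, 30, (6, 8, 8))
        out = normalize_percentile(x, 1.0, 99.8)
        lo = np.percentile(x, 1.0)
        hi = np.percentile(x, 99.8)
        expected = np.clip((x - lo) / (hi - lo), 0, 1)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)


def _render_nuclei(centers_um, shape, voxel=(1.0, 1.0, 1.0), radius=4.0, edge=0.8):
    """Flat-top nucleus blobs, same profile as the synthetic generator."""
    dz, dy, dx = voxel
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    img = np.zeros(shape, np.float32)
    for cz, cy, cx in centers_um:
        d = np.sqrt((zz * dz - cz) ** 2 + (yy * dy - cy) ** 2 + (xx * dx - cx) ** 2)
        img += np.exp(-0.5 * (np.maximum(d - radius, 0) / edge) ** 2)
    return np.clip(img, 0, 1)


class TestSegmentNuclei:
    def test_two_separated_nuclei_recovered(self):
        """Two 4-µm-radius nuclei 12 µm apart -> 2 labels, each covering its truth ball."""
        crop = _render_nuclei([(10, 10, 10), (10, 10, 22)], (20, 24, 34))
        labeled = segment_nuclei(crop, BackendConfig(), (1.0, 1.0, 1.0))
        assert labeled.n_objects == 2
        zz, yy, xx = np.mgrid[0:20, 0:24, 0:34].astype(float)
        for cz, cy, cx in [(10, 10, 10), (10, 10, 22)]:
            ball = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= 16
            ids, cnt = np.unique(labeled.labels[ball], return_counts=True)
            best = ids[np.argmax(cnt)]
            assert best > 0
            assert (labeled.labels[ball] == best).mean() >= 0.9

    def test_single_nucleus_single_label(self):
        crop = _render_nuclei([(8, 10, 10)], (16, 20, 20))
        assert segment_nuclei(crop, BackendConfig(), (1.0, 1.0, 1.0)).n_objects == 1

    def test_touching_pair_split_by_watershed(self):
        """Nuclei whose supports touch across a shallow valley are still split."""
        crop = _render_nuclei([(8, 10, 10), (8, 10, 18.5)], (16, 20, 30))
        labeled = segment_nuclei(crop, BackendConfig(), (1.0, 1.0, 1.0))
        assert labeled.n_objects == 2

    def test_empty_crop_zero_labels(self):
        labeled = segment_nuclei(np.zeros((4, 6, 6), np.float32), BackendConfig())
        assert labeled.n_objects == 0

    def test_unnormalized_input_warns(self):
        crop = _render_nuclei([(8, 10, 10)], (16, 20, 20)) * 5000
        with pytest.warns(UserWarning, match="normalized"):
            segment_nuclei(crop, BackendConfig(), (1.0, 1.0, 1.0))

    def test_anisotropic_voxels_give_same_nuclei(self):
        """Physical-unit parameters: halving z-sampling keeps both nuclei."""
        crop = _render_nuclei([(10, 10, 10), (10, 10, 22)], (10, 24, 34),
                              voxel=(2.0, 1.0, 1.0))
        labeled = segment_nuclei(crop, BackendConfig(), (2.0, 1.0, 1.0))
        assert labeled.n_objects == 2


def _ball_labels(radius_vox, shape):
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    c = tuple(s // 2 for s in shape)
    ball = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius_vox ** 2
    return ball.astype(np.int32)


class TestNucleusFeatures:
    def test_digital_ball_volume_and_symmetry(self):
        """Isotropic digital ball: volume == voxel count, eccentricity ~ 1."""
        labels = _ball_labels(3, (9, 9, 9))
        crop = (labels > 0).astype(np.float32) * 50
        lv = LabeledVolume(labels, (1.0, 1.0, 1.0))
        df = nucleus_features(lv, crop, organoid_label=4, channel="egfp")
        row = df.iloc[0]
        assert row["volume"] == pytest.approx(float((labels > 0).sum()))
        assert row["eccentricity"] == pytest.approx(1.0, abs=0.05)
        assert row["organoid_label"] == 4 and row["channel"] == "egfp"

    def test_prolate_ellipsoid_eccentricity(self):
        """Semi-axes (8,4,4) µm -> minor/major axis ratio ~ 0.5 (moments oracle)."""
        zz, yy, xx = np.mgrid[0:21, 0:11, 0:11].astype(float)
        ell = (((zz - 10) / 8) ** 2 + ((yy - 5) / 4) ** 2 + ((xx - 5) / 4) ** 2) <= 1
        labels = ell.astype(np.int32)
        lv = LabeledVolume(labels, (1.0, 1.0, 1.0))
        df = nucleus_features(lv, labels.astype(np.float32), 1)
        assert df.iloc[0]["eccentricity"] == pytest.approx(0.5, abs=0.05)

    def test_uniform_intensity_min_mean_max_equal(self):
        labels = _ball_labels(3, (9, 9, 9))
        crop = (labels > 0).astype(np.float32) * 123
        df = nucleus_features(LabeledVolume(labels, (1.0, 1.0, 1.0)), crop, 1)
        row = df.iloc[0]
        assert row["intensity_min"] == row["intensity_mean"] == row["intensity_max"] == 123

    def test_offset_shifts_to_well_frame(self):
        labels = _ball_labels(2, (7, 7, 7))
        crop = (labels > 0).astype(np.float32)
        df0 = nucleus_features(LabeledVolume(labels, (1.0, 1.0, 1.0)), crop, 1)
        df1 = nucleus_features(LabeledVolume(labels, (1.0, 1.0, 1.0)), crop, 1,
                               offset=(5, 10, 20))
        assert df1.iloc[0]["centroid_z"] == df0.iloc[0]["centroid_z"] + 5
        assert df1.iloc[0]["bbox_ymin"] == df0.iloc[0]["bbox_ymin"] + 10
        assert df1.iloc[0]["bbox_xmax"] == df0.iloc[0]["bbox_xmax"] + 20

    def test_shape_mismatch_rejected(self):
        labels = _ball_labels(2, (7, 7, 7))
        with pytest.raises(ValueError, match="shape"):
            nucleus_features(LabeledVolume(labels, (1, 1, 1)),
                             np.zeros((7, 7, 8), np.float32), 1)


class TestCropFrameRoundTrip:
    def test_crop_plus_offset_matches_full_frame_segmentation(self, small_well):
        """Nucleus centroids found in a padded crop map back onto the well frame."""
        from organoid3d.nuclei_segmentation import segment_organoid_nuclei
        from organoid3d.pipeline import segment_well_organoids
        from organoid3d.organoid_segmentation import SegmentationParams

        cfg, vol, truth = small_well
        _, orgs = segment_well_organoids(vol, SegmentationParams())
        assert len(orgs) == len(truth.organoids)
        row = orgs.iloc[0]
        t0, _, off0 = segment_organoid_nuclei(vol, row, BackendConfig(), (0, 1), pad_voxels=0)
        t4, _, off4 = segment_organoid_nuclei(vol, row, BackendConfig(), (0, 1), pad_voxels=4)
        # well-frame centroids agree between paddings for matched nuclei
        a = t0.sort_values(["channel", "centroid_z", "centroid_y", "centroid_x"])
        b = t4.sort_values(["channel", "centroid_z", "centroid_y", "centroid_x"])
        assert abs(len(a) - len(b)) <= 2  # boundary effects only
        n = min(len(a), len(b))
        if n:
            da = a[["centroid_y", "centroid_x"]].to_numpy()[:n]
            db = b[["centroid_y", "centroid_x"]].to_numpy()[:n]
            assert np.median(np.abs(da - db)) < 1.5

    def test_channel_order_permutation_is_independent(self, small_well):
        """Per-channel segmentation: channel order does not change any channel's nuclei."""
        from organoid3d.nuclei_segmentation import segment_organoid_nuclei
        from organoid3d.pipeline import segment_well_organoids
        from organoid3d.organoid_segmentation import SegmentationParams

        cfg, vol, truth = small_well
        _, orgs = segment_well_organoids(vol, SegmentationParams())
        row = orgs.iloc[0]
        t01, _, _ = segment_organoid_nuclei(vol, row, BackendConfig(), (0, 1))
        t10, _, _ = segment_organoid_nuclei(vol, row, BackendConfig(), (1, 0))
        for ch in ("egfp", "mcherry"):
            a = t01[t01["channel"] == ch].reset_index(drop=True)
            b = t10[t10["channel"] == ch].reset_index(drop=True)
            np.testing.assert_allclose(
                a[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(),
                b[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(),
            )
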