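"""Stage-1 organoid segmentation: cleaning, triangle threshold, labeling, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organoid3d.organoid_segmentation import (
    DegenerateHistogramError,
    LabeledVolume,
    SegmentationParams,
    clean_field,
    organoid_features,
    relabel_raster_order,
    segment_field,
    stitch_label_filter,
    triangle_threshold,
)
from organoid3d.plate_io import PlateLayout, WellVolume


def brute_force_triangle(image, nbins=256):
    """Independent geometric oracle: test every bin's exact point-line distance."""
    image = np.asarray(image)
    counts, edges = np.histogram(image.ravel(), bins=nbins,
                                 range=(image.min(), image.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    nz = np.flatnonzero(counts)
    tail = nz[-1] if (nz[-1] - peak) >= (peak - nz[0]) else nz[0]
    p1 = np.array([peak, counts[peak]], float)
    p2 = np.array([tail, counts[tail]], float)
    norm = np.linalg.norm(p2 - p1)
    best_i, best_d = None, -1.0
    rng_bins = range(min(peak, tail), max(peak, tail) + 1)
    for i in rng_bins:
        p = np.array([i, counts[i]], float)
        v1, v2 = p2 - p1, p - p1
        d = abs(v1[0] * v2[1] - v1[1] * v2[0]) / norm
        if d > best_d:
            best_d, best_i = d, i
    return float(centers[best_i])


class TestTriangleThreshold:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_geometric_oracle(self, seed):
        """Vectorized triangle equals per-bin point-line-distance enumeration."""
        rng = np.random.default_rng(seed)
        n_bg, n_fg = rng.integers(500, 5000), rng.integers(20, 500)
        img = np.concatenate([
            rng.normal(rng.uniform(10, 60), rng.uniform(2, 15), n_bg),
            rng.normal(rng.uniform(120, 250), rng.uniform(5, 30), n_fg),
        ])
        assert triangle_threshold(img) == pytest.approx(brute_force_triangle(img))

    def test_bimodal_threshold_between_modes(self, rng):
        img = np.concatenate([rng.normal(30, 3, 20000), rng.normal(200, 5, 800)])
        thr = triangle_threshold(img)
        assert 40 < thr < 195

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(np.full((10, 10), 7.0))


class TestCleanField:
    def test_hot_pixels_removed_blob_kept(self):
        """Isolated hot pixels below the opening size vanish; the blob survives."""
        field = np.zeros((1, 4, 40, 40), np.uint16)
        field[0, :, 10:26, 10:26] = 20000  # large blob
        hot = [(2, 33), (35, 5), (30, 34)]
        for y, x in hot:
            field[0, 1, y, x] = 30000
        out = clean_field(field, SegmentationParams())
        assert (out[0, :, 12:24, 12:24] == 20000).all()
        for y, x in hot:
            assert out[0, 1, y, x] == 0

    def test_all_zero_field_stays_zero(self):
        field = np.zeros((2, 3, 20, 20), np.uint16)
        assert clean_field(field).sum() == 0

    def test_clean_blob_unchanged_within_mask(self):
        field = np.zeros((1, 2, 30, 30), np.uint16)
        field[0, :, 5:25, 5:25] = 15000
        out = clean_field(field)
        # opening may round the blob's extreme corners; the interior is untouched
        np.testing.assert_array_equal(out[0, :, 7:23, 7:23], field[0, :, 7:23, 7:23])
        assert (out <= field).all()  # cleaning only ever zeroes pixels


def _sphere_field(centers, radius=6, intensity=200.0, background=10.0,
                  shape=(1, 12, 96, 96), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[0:shape[1], 0:shape[2], 0:shape[3]]
    field = np.full(shape, background, np.float32)
    truth = np.zeros(shape[1:], bool)
    for cz, cy, cx in centers:
        ball = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
        field[0][ball] = intensity
        truth |= ball
    if noise:
        field += rng.normal(0, noise, shape).astype(np.float32)
    return np.clip(field, 0, None), truth


class TestSegmentField:
    def test_single_sphere_recovered(self):
        field, truth = _sphere_field([(6, 48, 48)], noise=5.0)
        mask = segment_field(field, SegmentationParams(gaussian_sigma=(0.5, 1, 1)))
        assert mask[truth].mean() >= 0.95
        assert mask[~truth].mean() <= 0.01

    def test_empty_field_empty_mask(self):
        mask = segment_field(np.zeros((1, 4, 20, 20), np.float32))
        assert mask.dtype == bool and mask.sum() == 0

    def test_two_spheres_both_detected(self):
        field, truth = _sphere_field([(6, 24, 24), (6, 68, 68)], noise=3.0)
        mask = segment_field(field, SegmentationParams(gaussian_sigma=(0.5, 1, 1)))
        assert mask[truth].mean() >= 0.9
        assert mask[6, 24, 24] and mask[6, 68, 68]


def _stitch_layout(fr=1, fc=2, planes=8, h=24, w=24):
    return PlateLayout(rows=1, cols=1, field_grid=(fr, fc), planes_per_field=planes,
                       channels=("c0",), field_shape_px=(h, w),
                       voxel_size_um=(1.0, 1.0, 1.0))


class TestStitchLabelFilter:
    def test_sphere_straddling_fields_gets_one_label(self):
        """Stitching before labeling merges an organoid split across a border."""
        layout = _stitch_layout()
        zz, yy, xx = np.mgrid[0:8, 0:24, 0:48]
        ball = ((zz - 4) ** 2 + (yy - 12) ** 2 + (xx - 24) ** 2) <= 36
        masks = {0: ball[:, :, :24], 1: ball[:, :, 24:]}
        labeled = stitch_label_filter(masks, layout, min_volume_voxels=1)
        assert labeled.n_objects == 1

    def test_small_object_filtered_by_count(self):
        layout = _stitch_layout(fc=1, w=48)
        mask = np.zeros((8, 24, 48), bool)
        mask[2:6, 2:8, 2:8] = True     # 144 voxels
        mask[2:6, 12:18, 12:18] = True  # 144 voxels
        mask[3, 20, 40] = True          # 1 voxel
        labeled = stitch_label_filter({0: mask}, layout, min_volume_voxels=10)
        assert labeled.n_objects == 2

    def test_empty_masks_zero_labels(self):
        layout = _stitch_layout()
        labeled = stitch_label_filter({0: np.zeros((8, 24, 24), bool),
                                       1: np.zeros((8, 24, 24), bool)}, layout)
        assert labeled.n_objects == 0

    def test_inconsistent_shapes_rejected(self):
        layout = _stitch_layout()
        with pytest.raises(ValueError, match="shape"):
            stitch_label_filter({0: np.zeros((8, 24, 24), bool),
                                 1: np.zeros((8, 24, 20), bool)}, layout)

    def test_voxel_count_conserved_and_labels_raster_ordered(self, rng):
        layout = _stitch_layout(fc=1, w=24)
        mask = rng.random((8, 24, 24)) > 0.7
        labeled = stitch_label_filter({0: mask}, layout, min_volume_voxels=5)
        lab = labeled.labels
        n_fg = (lab > 0).sum()
        counts = np.bincount(lab.ravel())[1:]
        assert counts.sum() == n_fg
        assert (counts >= 5).all()
        firsts = [np.flatnonzero(lab.ravel() == k)[0] for k in range(1, lab.max() + 1)]
        assert firsts == sorted(firsts)


def _vol_from_labels(labels, voxel=(5.0, 1.0, 1.0), intensity=None, channels=("c0",)):
    nz, ny, nx = labels.shape
    layout = PlateLayout(rows=1, cols=1, field_grid=(1, 1), planes_per_field=nz,
                         channels=channels, field_shape_px=(ny, nx),
                         voxel_size_um=voxel)
    if intensity is None:
        intensity = (labels > 0).astype(np.uint16) * 100
    return WellVolume(np.stack([intensity] * len(channels)), layout)


class TestOrganoidFeatures:
    def test_solid_cuboid_closed_form(self):
        """A 4x10x10-voxel cuboid at (5,1,1) µm: 400 voxels -> 2000 µm³, solid."""
        labels = np.zeros((8, 20, 20), np.int32)
        labels[2:6, 5:15, 5:15] = 1
        vol = _vol_from_labels(labels)
        df = organoid_features(LabeledVolume(labels, (5.0, 1.0, 1.0)), vol)
        row = df.iloc[0]
        assert row["volume"] == pytest.approx(400 * 5.0)
        assert row["euler_number"] == 1
        assert row["solidity"] == pytest.approx(1.0)
        assert row["extent"] == pytest.approx(1.0)
        assert row["n_voxels"] == 400

    def test_interior_cavity_changes_volume_and_topology(self):
        """A hollow cuboid has volume < filled volume and a cavity-driven Euler number."""
        labels = np.zeros((10, 20, 20), np.int32)
        labels[2:8, 4:16, 4:16] = 1
        labels[4:6, 8:12, 8:12] = 0  # sealed interior cavity
        vol = _vol_from_labels(labels)
        df = organoid_features(LabeledVolume(labels, (5.0, 1.0, 1.0)), vol)
        row = df.iloc[0]
        assert row["volume"] < row["volume_filled"]
        assert row["euler_number"] == 2  # one component + one enclosed cavity

    def test_uniform_intensity_min_mean_max_equal(self):
        labels = np.zeros((4, 10, 10), np.int32)
        labels[1:3, 2:8, 2:8] = 1
        vol = _vol_from_labels(labels, intensity=(labels > 0).astype(np.uint16) * 77)
        df = organoid_features(LabeledVolume(labels, (5.0, 1.0, 1.0)), vol)
        row = df.iloc[0]
        assert row["intensity_min_c0"] == row["intensity_mean_c0"] == row["intensity_max_c0"] == 77

    def test_volume_chain_inequality_on_random_blobs(self, rng):
        """volume <= filled <= convex <= bbox for every labeled object."""
        from scipy import ndimage

        blob = ndimage.binary_dilation(rng.random((12, 30, 30)) > 0.97,
                                       iterations=2)
        labels, _ = ndimage.label(blob)
        labels = relabel_raster_order(labels)
        vol = _vol_from_labels(labels, voxel=(2.0, 1.0, 1.0))
        df = organoid_features(LabeledVolume(labels, (2.0, 1.0, 1.0)), vol)
        eps = 1e-9
        assert (df["volume"] <= df["volume_filled"] + eps).all()
        assert (df["volume_filled"] <= df["volume_convex"] + eps).all()
        assert (df["volume_convex"] <= df["volume_bbox"] + eps).all()
        assert ((df["solidity"] > 0) & (df["solidity"] <= 1 + eps)).all()

    def test_shape_mismatch_rejected(self):
        labels = np.ones((4, 10, 10), np.int32)
        vol = _vol_from_labels(np.ones((4, 12, 10), np.int32))
        with pytest.raises(ValueError, match="shape"):
            organoid_features(LabeledVolume(labels, (1, 1, 1)), vol)
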