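"""Cell identification, watershed behavior, border removal, features, filters."""

import numpy as np
import pandas as pd
import pytest

from cellcoloc.io import ChannelStack, LabelMap
from cellcoloc.segmentation import (
    FilterSpec,
    apply_filters,
    compute_features,
    remove_border_objects,
    segment_cells,
)


class TestSegmentCells:
    def test_touching_discs_split_by_watershed(self, disc_pair_image):
        lm = segment_cells(disc_pair_image, 100, use_watershed=True)
        assert lm.n_objects == 2

    def test_touching_discs_merge_without_watershed(self, disc_pair_image):
        lm = segment_cells(disc_pair_image, 100, use_watershed=False)
        assert lm.n_objects == 1

    def test_watershed_never_merges(self, rng):
        for _ in range(5):
            img = (rng.random((40, 40)) > 0.8) * 200.0
            before = segment_cells(img, 100, use_watershed=False).n_objects
            after = segment_cells(img, 100, use_watershed=True).n_objects
            assert after >= before

    def test_prewatershed_filter_removes_large_blob(self):
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        disc = (yy - 30) ** 2 + (xx - 30) ** 2 <= 100  # area 317
        img[disc] = 200.0
        img[60:110, 10:110] = 200.0  # 5000-px blob
        assert int(disc.sum()) == 317
        lm = segment_cells(img, 100, use_watershed=True, prewatershed_max_area=1000)
        assert lm.n_objects == 1
        assert int((lm.labels > 0).sum()) == 317

    def test_labels_in_raster_scan_order(self):
        img = np.zeros((20, 20))
        img[12:15, 2:5] = 9  # lower-left, appears later in raster order
        img[2:5, 12:15] = 9  # upper-right, first
        lm = segment_cells(img, 1)
        assert lm.labels[3, 13] == 1 and lm.labels[13, 3] == 2


class TestRemoveBorderObjects:
    def _three_objects(self):
        lab = np.zeros((16, 16), dtype=np.int32)
        lab[0:3, 4:7] = 1  # touches row 0
        lab[6:9, 2:5] = 2
        lab[10:13, 9:12] = 3
        return LabelMap(lab)

    def test_border_object_removed_and_renumbered(self):
        out = remove_border_objects(self._three_objects())
        assert out.n_objects == 2
        assert sorted(np.unique(out.labels)) == [0, 1, 2]
        assert out.labels[7, 3] == 1  # raster order preserved

    def test_interior_objects_unchanged(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:4, 2:4] = 1
        lab[6:8, 6:8] = 2
        out = remove_border_objects(LabelMap(lab))
        assert np.array_equal(out.labels, lab)

    def test_full_frame_object_leaves_nothing(self):
        lab = np.ones((8, 8), dtype=np.int32)
        out = remove_border_objects(LabelMap(lab))
        assert out.n_objects == 0


class TestComputeFeatures:
    def test_square_geometry_hand_counts(self):
        lab = np.zeros((12, 12), dtype=np.int32)
        lab[5:8, 5:8] = 1  # 3x3 solid square
        feats = compute_features(LabelMap(lab))
        row = feats.iloc[0]
        assert row["area"] == 9
        assert row["centroid_x"] == pytest.approx(6.0)
        assert row["centroid_y"] == pytest.approx(6.0)
        assert row["perimeter"] == pytest.approx(12.0)  # traced pixel edges
        assert row["circularity"] == pytest.approx(4 * np.pi * 9 / 144)
        assert row["solidity"] == pytest.approx(1.0)

    def test_features_match_brute_force_accumulation(self, rng):
        lab = np.zeros((25, 25), dtype=np.int32)
        yy, xx = np.mgrid[0:25, 0:25]
        lab[(yy - 8) ** 2 + (xx - 8) ** 2 <= 20] = 1
        lab[(yy - 18) ** 2 / 12 + (xx - 17) ** 2 / 4 <= 1] = 2
        img = rng.integers(0, 1000, (25, 25)).astype(np.uint16)
        stack = ChannelStack([img], 16, "r1", "reporter1")
        feats = compute_features(LabelMap(lab), [stack])
        for k in (1, 2):
            mask = lab == k
            row = feats[feats["label"] == k].iloc[0]
            assert row["area"] == mask.sum()
            assert row["centroid_x"] == pytest.approx(np.argwhere(mask)[:, 1].mean())
            assert row["centroid_y"] == pytest.approx(np.argwhere(mask)[:, 0].mean())
            assert row["mean_intensity_reporter1"] == pytest.approx(img[mask].mean())
            assert row["median_intensity_reporter1"] == pytest.approx(
                np.median(img[mask])
            )
            assert row["mean_bgnd_ratio_reporter1"] == pytest.approx(
                img[mask].mean() / img[lab == 0].mean()
            )

    def test_bgnd_ratio_exact_on_constants(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[3:6, 3:6] = 1
        img = np.full((10, 10), 10, dtype=np.uint16)
        img[3:6, 3:6] = 50
        stack = ChannelStack([img], 16, "r1", "reporter1")
        feats = compute_features(LabelMap(lab), [stack])
        assert feats["mean_bgnd_ratio_reporter1"].iloc[0] == 5.0
        assert feats["median_bgnd_ratio_reporter1"].iloc[0] == 5.0

    def test_zero_background_gives_nan_ratio(self):
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[2:5, 2:5] = 1
        img = np.zeros((8, 8), dtype=np.uint16)
        img[2:5, 2:5] = 7
        stack = ChannelStack([img], 16, "r1", "reporter1")
        feats = compute_features(LabelMap(lab), [stack])
        assert np.isnan(feats["mean_bgnd_ratio_reporter1"].iloc[0])


class TestApplyFilters:
    @pytest.fixture
    def areas_table(self):
        return pd.DataFrame({"label": [1, 2, 3], "area": [5.0, 40.0, 900.0]})

    def test_area_interval_retains_one(self, areas_table):
        got = apply_filters(areas_table, [FilterSpec("Area", 10, 500)])
        assert got == {2}

    def test_no_specs_retains_all(self, areas_table):
        assert apply_filters(areas_table, []) == {1, 2, 3}

    def test_bounds_inclusive(self, areas_table):
        assert apply_filters(areas_table, [FilterSpec("Area", 5, 40)]) == {1, 2}

    def test_intensity_filter_on_named_channel(self):
        feats = pd.DataFrame(
            {"label": [1, 2], "mean_bgnd_ratio_reporter1": [1.1, 3.0]}
        )
        spec = FilterSpec("MeanBgndRatio", 2.0, np.inf, channel="reporter1")
        assert apply_filters(feats, [spec]) == {2}

    def test_filters_order_independent(self, rng):
        feats = pd.DataFrame(
            {"label": np.arange(1, 21),
             "area": rng.integers(1, 100, 20).astype(float),
             "circularity": rng.uniform(0, 1, 20)}
        )
        s1 = [FilterSpec("Area", 10, 80), FilterSpec("Circularity", 0.2, 0.9)]
        assert apply_filters(feats, s1) == apply_filters(feats, s1[::-1])

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            FilterSpec("Banana", 0, 1)

    def test_physical_filter_rejects_channel(self):
        with pytest.raises(ValueError, match="no channel"):
            FilterSpec("Area", 0, 1, channel="reporter1")

    def test_intensity_filter_requires_channel(self):
        with pytest.raises(ValueError, match="needs a channel"):
            FilterSpec("MeanIntensity", 0, 1)
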