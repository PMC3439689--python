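import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from myocfc import (
    Channel,
    SegmentationParams,
    label_regions,
    remove_background,
    segment_channel,
    threshold_plane,
)
from tests.conftest import make_plane
from tests.oracles import flood_fill_regions, reference_opening

planes = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(st.integers(4, 24), st.integers(4, 24)),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestParams:
    @pytest.mark.parametrize(
        "radius,threshold", [(-1, 0.5), (2, -0.1), (2, 1.5)]
    )
    def test_invalid_parameters_rejected(self, radius, threshold):
        with pytest.raises(ValueError):
            SegmentationParams(radius, threshold, Channel.DAPI_BLUE)


class TestRemoveBackground:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(3)
        plane = make_plane(rng.random((16, 16)))
        np.testing.assert_array_equal(
            remove_background(plane, 0).pixels, plane.pixels
        )

    def test_isolated_bright_pixel_suppressed(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = remove_background(make_plane(img), 2)
        assert out.pixels[7, 7] == 0.0
        assert out.pixels.max() == 0.0

    def test_bright_disk_interior_survives_smaller_element(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 6**2
        img[disk] = 0.9
        out = remove_background(make_plane(img), 3)
        assert out.pixels[32, 32] == 0.9
        assert out.pixels[disk].max() == 0.9

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_direct_erode_then_dilate_reference(self, radius):
        rng = np.random.default_rng(11)
        img = rng.random((20, 20))
        out = remove_background(make_plane(img), radius)
        np.testing.assert_allclose(out.pixels, reference_opening(img, radius))

    @given(planes)
    def test_opening_is_anti_extensive_and_idempotent(self, img):
        plane = make_plane(img)
        once = remove_background(plane, 2)
        assert np.all(once.pixels <= img + 1e-12)
        twice = remove_background(once, 2)
        np.testing.assert_allclose(twice.pixels, once.pixels)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            remove_background(make_plane(np.zeros((4, 4))), -1)


class TestThreshold:
    def test_strict_inequality_at_the_threshold(self):
        plane = make_plane(np.full((4, 4), 0.5))
        assert threshold_plane(plane, 0.5).sum() == 0
        assert threshold_plane(plane, 0.49).all()

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(5)
        img = rng.random((10, 10))
        plane = make_plane(img)
        assert threshold_plane(plane, 1.0).sum() == 0
        assert threshold_plane(plane, 0.0).sum() == (img > 0).sum()

    def test_foreground_count_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(17)
        img = rng.random((32, 32))
        for t in (0.1, 0.5, 0.9):
            mask = threshold_plane(make_plane(img), t)
            assert mask.sum() == sum(v > t for v in img.ravel())

    @given(planes, st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_raising_threshold_never_grows_foreground(self, img, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        plane = make_plane(img)
        assert threshold_plane(plane, hi).sum() <= threshold_plane(plane, lo).sum()


class TestLabelRegions:
    def test_empty_mask_gives_no_regions(self):
        assert label_regions(np.zeros((5, 5), dtype=bool)) == []

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        regions = label_regions(mask)
        assert len(regions) == 1
        assert regions[0].area_px == 2
        assert regions[0].centroid == (1.5, 1.5)

    def test_disjoint_rectangles_match_flood_fill_oracle(self):
        mask = np.zeros((64, 64), dtype=bool)
        boxes = [(2, 2, 6, 10), (2, 20, 4, 25), (30, 30, 40, 33),
                 (50, 5, 55, 60), (10, 40, 12, 42)]
        for r0, c0, r1, c1 in boxes:
            mask[r0:r1, c0:c1] = True
        regions = label_regions(mask)
        oracle = flood_fill_regions(mask)
        assert len(regions) == len(oracle) == 5
        got = sorted((r.area_px, r.centroid) for r in regions)
        want = sorted((o["area"], o["centroid"]) for o in oracle)
        assert got == want

    def test_labels_are_contiguous_from_one(self):
        rng = np.random.default_rng(23)
        mask = rng.random((32, 32)) > 0.7
        regions = label_regions(mask)
        assert [r.label for r in regions] == list(range(1, len(regions) + 1))

    @given(hnp.arrays(dtype=bool, shape=st.tuples(st.integers(1, 16), st.integers(1, 16))))
    def test_labeling_partitions_the_foreground(self, mask):
        regions = label_regions(mask)
        assert sum(r.area_px for r in regions) == int(mask.sum())
        all_coords = set()
        for r in regions:
            coords = set(map(tuple, r.coords))
            assert not (coords & all_coords)  # disjoint
            all_coords |= coords

    def test_boundary_is_ordered_subset_of_region(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 2:10] = True
        mask[5, 5] = False  # interior hole must not enter the outer boundary
        region = label_regions(mask)[0]
        boundary = {tuple(p) for p in region.boundary}
        members = set(map(tuple, region.coords))
        assert boundary <= members
        # the outer rectangle perimeter is fully traced
        perimeter = {
            (r, c)
            for r in range(3, 9)
            for c in range(2, 10)
            if r in (3, 8) or c in (2, 9)
        }
        assert perimeter <= boundary
        assert (5, 5) not in boundary

    def test_single_pixel_boundary_is_itself(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        region = label_regions(mask)[0]
        np.testing.assert_array_equal(region.boundary, [[2, 3]])

    def test_hole_does_not_count_toward_area(self):
        mask = np.ones((7, 7), dtype=bool)
        mask[3, 3] = False
        region = label_regions(mask)[0]
        assert region.area_px == 48


class TestSegmentChannel:
    def test_all_black_plane_yields_nothing(self):
        params = SegmentationParams(2, 0.3, Channel.DAPI_BLUE)
        assert segment_channel(make_plane(np.zeros((32, 32))), params) == []

    def test_ten_separated_disks_found_exactly(self):
        img = np.zeros((128, 128))
        rr, cc = np.mgrid[:128, :128]
        centers = [(r, c) for r in (15, 50, 85, 110) for c in (15, 55, 95)][:10]
        for r0, c0 in centers:
            img[(rr - r0) ** 2 + (cc - c0) ** 2 <= 5**2] = 0.8
        params = SegmentationParams(1, 0.3, Channel.DAPI_BLUE)
        assert len(segment_channel(make_plane(img), params)) == 10
        high = SegmentationParams(1, 0.9, Channel.DAPI_BLUE)
        assert segment_channel(make_plane(img), high) == []

    def test_channel_mismatch_rejected(self):
        params = SegmentationParams(1, 0.3, Channel.MHC_RED)
        with pytest.raises(ValueError):
            segment_channel(make_plane(np.zeros((8, 8)), Channel.DAPI_BLUE), params)
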