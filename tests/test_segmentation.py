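"""Segmentation chain: excess-green index, Otsu, closing, blob moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from maizegap.segmentation import (
    PlantBlob,
    blob_centroid,
    close_mask,
    excess_green,
    extract_blobs,
    otsu_binarize,
)


def between_class_variances(u8: np.ndarray) -> np.ndarray:
    """Brute-force between-class variance at every 256-bin split point."""
    hist = np.bincount(u8.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256)
    out = np.full(256, -1.0)
    for t in range(255):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (levels[: t + 1] * p[: t + 1]).sum() / w0
        m1 = (levels[t + 1 :] * p[t + 1 :]).sum() / w1
        out[t] = w0 * w1 * (m0 - m1) ** 2
    return out


def assert_otsu_optimal(u8: np.ndarray, thr: int, mask: np.ndarray) -> None:
    """The threshold must attain the brute-force maximal between-class
    variance (ties across empty histogram gaps produce identical masks)."""
    variances = between_class_variances(u8)
    oracle_t = int(np.argmax(variances))
    assert variances[thr] == pytest.approx(variances[oracle_t], rel=1e-12)
    assert np.array_equal(mask, u8 > oracle_t)


def label_oracle_8conn(mask: np.ndarray) -> list[set]:
    """Brute-force 8-connected component labeling by flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


class TestExcessGreen:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((60, 120, 40), 140), ((77, 77, 77), 0), ((255, 0, 255), -510), ((0, 255, 0), 510)],
    )
    def test_pointwise(self, pixel, expected):
        img = np.array(pixel, dtype=np.uint8).reshape(1, 1, 3)
        assert excess_green(img)[0, 0] == expected

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            excess_green(np.zeros((4, 4)))

    @given(
        img=hnp.arrays(np.uint8, (5, 7, 3), elements=st.integers(0, 51)),
        scale=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_channel_scale(self, img, scale):
        assert np.array_equal(excess_green(img * scale), scale * excess_green(img).astype(np.int64))


class TestOtsu:
    def test_two_valued_map(self):
        values = np.zeros((10, 10), dtype=int)
        values.ravel()[:40] = 200  # 40% foreground
        thr, mask = otsu_binarize(values)
        assert 0 <= thr < 255
        assert mask.mean() == pytest.approx(0.40)

    def test_bimodal_threshold_between_modes(self, rng):
        low = rng.normal(20, 3, 600).clip(0, 255)
        high = rng.normal(200, 3, 400).clip(0, 255)
        values = np.concatenate([low, high]).reshape(25, 40)
        thr, mask = otsu_binarize(values)
        # threshold (on the rescaled 0-255 scale) separates the two modes
        assert mask.sum() == 400
        assert 20 < thr < 230

    def test_constant_map_raises(self):
        with pytest.raises(ValueError):
            otsu_binarize(np.full((4, 4), 7))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_scan(self, seed):
        r = np.random.default_rng(seed)
        values = r.integers(0, 256, size=(16, 16))
        if np.unique(values).size < 2:
            return
        thr, mask = otsu_binarize(values)
        from maizegap.segmentation import _rescale_u8

        assert_otsu_optimal(_rescale_u8(values), thr, mask)


class TestClosing:
    def test_fills_interior_hole(self):
        mask = np.ones((9, 9), dtype=bool)
        mask[4, 4] = False
        assert close_mask(mask, 3).all()

    def test_empty_mask_unchanged(self):
        mask = np.zeros((6, 6), dtype=bool)
        assert not close_mask(mask, 5).any()

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            close_mask(np.zeros((3, 3), dtype=bool), 4)

    @given(mask=hnp.arrays(np.bool_, (12, 12)), k=st.sampled_from([1, 3, 5]))
    @settings(max_examples=60, deadline=None)
    def test_extensive_and_idempotent(self, mask, k):
        once = close_mask(mask, k)
        assert (once | mask).sum() == once.sum()  # output superset of input
        assert np.array_equal(close_mask(once, k), once)


class TestBlobs:
    def test_area_filter(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:17, 2:12] = True  # area 150
        mask[25:27, 25:29] = True  # area 8
        blobs = extract_blobs(mask, min_area_px=20)
        assert len(blobs) == 1
        assert blobs[0].area == 150

    def test_empty_mask(self):
        assert extract_blobs(np.zeros((5, 5), dtype=bool), 1) == []

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[[0, 1, 2], [0, 1, 2]] = True
        assert len(extract_blobs(mask, 1)) == 1

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_components_match_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((14, 14)) < 0.35
        blobs = extract_blobs(mask, 1)
        oracle = label_oracle_8conn(mask)
        got = sorted(sorted((y, x) for x, y in b.pixels) for b in blobs)
        want = sorted(sorted(c) for c in oracle)
        assert got == want

    def test_row_major_ordering(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[15:18, 1:4] = True
        mask[1:4, 10:13] = True
        blobs = extract_blobs(mask, 1)
        assert blobs[0].centroid[1] < blobs[1].centroid[1]


class TestCentroid:
    @pytest.mark.parametrize(
        "pixels, expected",
        [
            ([(x, y) for x in range(4) for y in range(4)], (1.5, 1.5)),
            ([(7, 3)], (7.0, 3.0)),
            ([(0, 0), (1, 0), (0, 1)], (1 / 3, 1 / 3)),
        ],
    )
    def test_examples(self, pixels, expected):
        blob = PlantBlob.from_pixels(np.array(pixels))
        assert blob_centroid(blob) == pytest.approx(expected)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None)
    def test_equals_pixel_mean(self, seed):
        r = np.random.default_rng(seed)
        pts = np.unique(r.integers(0, 30, size=(20, 2)), axis=0)
        blob = PlantBlob.from_pixels(pts)
        assert blob_centroid(blob) == pytest.approx(tuple(pts.mean(axis=0)))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            PlantBlob.from_pixels(np.empty((0, 2)))
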