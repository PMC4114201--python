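import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import random_star_polygon, spillover_bruteforce
from tractquant import (
    BinaryMask,
    ImageSection,
    PolygonROI,
    ValidationError,
    compute_threshold,
    count_labeled,
    expand_spillover_box,
    generate_injection_series,
    place_background_boxes,
    quantify_section,
    rasterize,
    summarize_injection,
)
from tractquant.injection import SectionQuant, ThresholdSpec, initial_spillover_box
from tractquant.image_model import BoxROI


def make_section(tracer: np.ndarray, **kw) -> ImageSection:
    tracer = np.asarray(tracer, dtype=np.uint8)
    kw.setdefault("pixel_size_um", 0.742)
    kw.setdefault("thickness_um", 80.0)
    return ImageSection(
        channels={"TRITC": tracer, "Nissl": np.zeros_like(tracer)}, **kw
    )


class TestBackgroundBoxes:
    def test_full_frame_box_size(self):
        # 1% of a 2048 x 2048 frame is 41943 px; the square side rounds to 205
        section = make_section(np.zeros((2048, 2048)))
        empty_roi = BinaryMask(np.zeros((2048, 2048), dtype=bool))
        boxes = place_background_boxes(section, empty_roi)
        assert len(boxes) == 3
        for b in boxes:
            assert b.width == b.height == 205
        assert not boxes[0].overlaps(boxes[1])
        assert not boxes[0].overlaps(boxes[2])
        assert not boxes[1].overlaps(boxes[2])

    def test_small_image_avoids_corner_roi(self):
        section = make_section(np.zeros((100, 100)))
        grid = np.zeros((100, 100), dtype=bool)
        grid[:15, :15] = True  # ROI blocks the top-left corner
        boxes = place_background_boxes(section, BinaryMask(grid))
        assert len(boxes) == 3
        for b in boxes:
            assert b.area_px == 100  # 1% of 100x100, a 10x10 square
            rs, cs = b.slices()
            assert not grid[rs, cs].any()

    def test_explicit_positions_override_roi(self, caplog):
        section = make_section(np.zeros((100, 100)))
        grid = np.zeros((100, 100), dtype=bool)
        grid[40:60, 40:60] = True
        with caplog.at_level(logging.WARNING):
            boxes = place_background_boxes(
                section, BinaryMask(grid), positions=[(45, 45), (0, 0), (80, 80)]
            )
        assert len(boxes) == 3
        assert "override" in caplog.text

    def test_roi_everywhere_errors(self):
        section = make_section(np.zeros((50, 50)))
        grid = np.ones((50, 50), dtype=bool)
        with pytest.raises(ValidationError, match="smaller box fraction"):
            place_background_boxes(section, BinaryMask(grid))


class TestComputeThreshold:
    def test_constant_pixels(self):
        spec = compute_threshold(np.full(20, 10.0))
        assert spec.threshold == 10.0
        assert spec.sd == 0.0
        assert not spec.capped

    def test_sample_sd_uses_n_minus_1(self):
        spec = compute_threshold(np.array([0.0, 0.0, 20.0, 20.0]))
        assert spec.mean == 10.0
        assert spec.sd == pytest.approx(math.sqrt(400.0 / 3.0))  # 11.547
        assert spec.threshold == pytest.approx(10.0 + 2 * math.sqrt(400.0 / 3.0))
        assert not spec.capped

    def test_upper_bound_cap(self):
        # mean 200, sample SD exactly 40 -> primary rule gives 280 > 255,
        # so the upper-bound rule applies: 255 - 2*40 = 175
        pixels = np.array([160.0, 160.0, 200.0, 240.0, 240.0])
        spec = compute_threshold(pixels)
        assert spec.mean == 200.0
        assert spec.sd == 40.0
        assert spec.threshold == 175.0
        assert spec.capped

    def test_too_few_pixels(self):
        with pytest.raises(ValidationError, match="at least 2"):
            compute_threshold(np.array([5.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 80), min_size=3, max_size=30),
        st.integers(1, 40),
    )
    def test_additive_shift_moves_threshold_by_same_amount(self, values, c):
        base = compute_threshold(np.array(values, dtype=float))
        if base.threshold + c > 255 or max(values) + c > 255:
            return  # keep clear of the cap; monotonicity holds below it
        shifted = compute_threshold(np.array(values, dtype=float) + c)
        assert not shifted.capped
        assert shifted.threshold == pytest.approx(base.threshold + c)


class TestCountLabeled:
    def test_strictly_above(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        mask = BinaryMask(np.ones((10, 10), dtype=bool))
        assert count_labeled(img, mask, 100.0) == 0

    def test_direct_count(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        grid = np.zeros((10, 10), dtype=bool)
        grid[:5, :10] = True  # 50-px mask
        img[0, :7] = 255  # 7 bright pixels inside
        img[9, :] = 255  # bright outside the mask: ignored
        assert count_labeled(img, BinaryMask(grid), 100.0) == 7

    def test_matches_double_loop(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        grid = rng.random((64, 64)) < 0.4
        expected = sum(
            1
            for y in range(64)
            for x in range(64)
            if grid[y, x] and img[y, x] > 128
        )
        assert count_labeled(img, BinaryMask(grid), 128) == expected


def _rect_roi(x0, y0, x1, y1):
    return PolygonROI(vertices=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


class TestExpandSpilloverBox:
    def test_quiet_image_keeps_initial_box(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        mask = rasterize(_rect_roi(20, 20, 44, 44), (64, 64))
        init, _ = initial_spillover_box(mask, (64, 64))
        res = expand_spillover_box(img, mask, 100.0)
        assert res.box == init
        assert res.spillover_px == 0
        assert res.n_iterations == 0

    def test_bright_bar_expands_only_right_side(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        mask = rasterize(_rect_roi(20, 20, 44, 44), (64, 64))
        init, _ = initial_spillover_box(mask, (64, 64))
        # 3-px-thick vertical bar crossing the initial right side, spanning
        # 10 middle rows (enough to trip the 10% side rule on the right side
        # but not on the top or bottom strips)
        rows = slice(27, 37)
        img[rows, init.right - 1 : init.right + 2] = 255
        res = expand_spillover_box(img, mask, 100.0)
        assert res.box.left == init.left
        assert res.box.top == init.top
        assert res.box.bottom == init.bottom
        assert res.box.right == init.right + 3  # one px past the bar
        assert res.spillover_px == 30
        assert not res.hit_border

    def test_border_stop_is_flagged(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        mask = rasterize(_rect_roi(20, 20, 44, 44), (64, 64))
        init, _ = initial_spillover_box(mask, (64, 64))
        img[27:37, init.right - 1 :] = 255  # bar running into the border
        res = expand_spillover_box(img, mask, 100.0)
        assert res.box.right == 64
        assert res.hit_border

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_side_rule(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 60, (64, 64)).astype(np.uint8)
        # scatter bright blobs, some inside and some outside the ROI
        for _ in range(rng.integers(2, 6)):
            y, x = rng.integers(4, 60, 2)
            h, w = rng.integers(2, 8, 2)
            img[y : y + h, x : x + w] = 200
        verts = random_star_polygon(rng, center=(32, 32), radius=rng.uniform(8, 14))
        mask = rasterize(PolygonROI(vertices=verts), (64, 64))
        res = expand_spillover_box(img, mask, 100.0)
        (l, r, t, b), spill = spillover_bruteforce(img, mask.grid, 100.0)
        assert (res.box.left, res.box.right, res.box.top, res.box.bottom) == (l, r, t, b)
        assert res.spillover_px == spill


class TestQuantifySection:
    def test_noiseless_closed_loop_is_exact(self):
        sections, truth = generate_injection_series(
            1, [0.10], background_sd=0.0, seed=11
        )
        section, roi = sections[0]
        q = quantify_section(section, roi)
        assert q.labeled_fraction == truth.section_fractions[0]
        assert q.labeled_fraction == pytest.approx(0.10, abs=1e-3)
        assert q.spillover_px == 0

    def test_blank_section_labels_little(self):
        rng = np.random.default_rng(5)
        img = np.clip(rng.normal(20, 5, (128, 128)), 0, 255).astype(np.uint8)
        section = make_section(img)
        roi = _rect_roi(40, 40, 90, 90)
        q = quantify_section(section, roi)
        # mean + 2*SD cuts the Gaussian background at the ~2.3% tail
        assert q.labeled_fraction <= 0.05

    def test_saturated_roi_trips_the_cap(self):
        img = np.full((128, 128), 20, dtype=np.uint8)
        roi = _rect_roi(24, 24, 104, 104)  # 6400 px ROI vs three 163-px boxes
        mask = rasterize(roi, (128, 128))
        img[mask.grid] = 255
        q = quantify_section(make_section(img), roi)
        assert q.threshold_spec.capped
        assert q.labeled_fraction == pytest.approx(1.0)

    def test_missing_tracer_channel(self):
        section = make_section(np.zeros((32, 32)))
        with pytest.raises(ValidationError, match="tracer channel"):
            quantify_section(section, _rect_roi(5, 5, 20, 20), tracer_channel="FITC")


def _quant(idx, roi_px, labeled, spill=0):
    spec = ThresholdSpec(mean=20.0, sd=5.0, threshold=30.0, capped=False)
    return SectionQuant(
        section_index=idx,
        roi_area_px=roi_px,
        threshold_spec=spec,
        labeled_px_in_roi=labeled,
        spillover_px=spill,
        final_box=BoxROI(0, 10, 0, 10),
    )


class TestSummarizeInjection:
    def test_single_section_identity(self):
        s = summarize_injection([_quant(0, 1000, 100)], 80.0, 0.742, 1)
        assert s.volume_fraction_pct == pytest.approx(10.0)
        assert s.epicenter_area_pct == pytest.approx(10.0)
        assert s.epicenter_section_index == 0

    def test_two_sections_weighted_mean(self):
        s = summarize_injection([_quant(0, 1000, 200), _quant(1, 1000, 0)], 80.0, 0.742, 2)
        assert s.volume_fraction_pct == pytest.approx(10.0)
        assert s.epicenter_section_index == 0
        assert s.epicenter_area_pct == pytest.approx(20.0)

    def test_coverage_rule_boundary(self):
        quants = [_quant(i, 1000, 10) for i in range(7)]
        s = summarize_injection(quants, 80.0, 0.742, 10)
        assert s.ap_coverage_fraction == pytest.approx(0.7)
        assert s.coverage_ok
        s6 = summarize_injection(quants[:6], 80.0, 0.742, 10)
        assert not s6.coverage_ok

    def test_spillover_volume_units(self):
        s = summarize_injection([_quant(0, 1000, 100, spill=50)], 80.0, 2.0, 1)
        assert s.total_spillover_volume_um3 == pytest.approx(50 * 4.0 * 80.0)

    def test_order_invariance(self):
        quants = [_quant(i, 1000 + 7 * i, 10 * i) for i in range(5)]
        fwd = summarize_injection(quants, 80.0, 0.742, 5)
        rev = summarize_injection(quants[::-1], 80.0, 0.742, 5)
        assert fwd.volume_fraction_pct == pytest.approx(rev.volume_fraction_pct)
        assert fwd.epicenter_section_index == rev.epicenter_section_index

    def test_empty_roi_section_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty ROI"):
            s = summarize_injection([_quant(0, 1000, 100), _quant(1, 0, 0)], 80.0, 0.742, 2)
        assert s.n_sections == 1
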