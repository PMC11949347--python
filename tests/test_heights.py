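"""Thresholding, segmentation, per-frame and per-bout maximum height."""
import math

import numpy as np
import pytest

import wingflap as wf
from wingflap.heights import FrameHeight

from conftest import random_depth_frame


def brute_force_frame_max(frame, mask, camera_height):
    """Exhaustive double-loop scan: height and first peak in row-major order."""
    best = None
    rows, cols = frame.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                h = camera_height - frame[r, c]
                if best is None or h > best[0]:
                    best = (h, (r, c))
    return best


def brute_force_components(mask):
    """Pure-python 8-connected labelling by BFS."""
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < rows and 0 <= xx < cols
                                    and mask[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


class TestFloorThreshold:
    def test_study_values(self):
        assert wf.floor_threshold(250.0, 5.0) == 245.0

    def test_degenerate_clearance_rejected(self):
        with pytest.raises(ValueError):
            wf.floor_threshold(250.0, 250.0)
        with pytest.raises(ValueError):
            wf.floor_threshold(250.0, 0.0)

    def test_arithmetic(self):
        assert math.isclose(wf.floor_threshold(248.7, 5.0), 243.7)


class TestSegmentation:
    def test_floor_only_gives_empty_mask(self, small_rig):
        frame = wf.render_floor_frames(small_rig, 1)[0]
        m = wf.segment_hen(frame, 245.0)
        assert m.empty and m.n_foreground == 0

    def test_strict_threshold_boundary(self):
        frame = np.full((5, 5), 250.0)
        frame[2, 2] = 244.9
        frame[1, 1] = 245.0
        m = wf.segment_hen(frame, 245.0, min_component_px=1)
        assert m.mask[2, 2] and not m.mask[1, 1]
        assert m.n_foreground == 1

    def test_invalid_pixels_never_foreground(self):
        frame = np.full((5, 5), 250.0)
        frame[0, 0] = wf.INVALID_DEPTH     # numerically < threshold
        m = wf.segment_hen(frame, 245.0)
        assert not m.mask[0, 0]

    def test_speckle_removed_by_component_size(self):
        frame = np.full((20, 20), 250.0)
        frame[3, 3] = 200.0                               # isolated speckle
        frame[10:14, 10:14] = 200.0                       # real object
        m = wf.segment_hen(frame, 245.0, min_component_px=5)
        assert not m.mask[3, 3]
        assert m.mask[10:14, 10:14].all()

    def test_component_filter_matches_bruteforce_labelling(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            frame = np.full((20, 20), 250.0)
            frame[rng.random((20, 20)) < 0.15] = 200.0
            raw = (frame > 0) & (frame < 245.0)
            for k in (1, 3, 5):
                expected = np.zeros_like(raw)
                for comp in brute_force_components(raw):
                    if len(comp) >= k:
                        for y, x in comp:
                            expected[y, x] = True
                got = wf.segment_hen(frame, 245.0, min_component_px=k).mask
                assert np.array_equal(got, expected)

    def test_prefilter_rejects_hot_pixel_keeps_blob(self):
        frame = np.full((20, 20), 250.0)
        frame[2, 2] = 200.0
        frame[8:14, 8:14] = 210.0
        m = wf.segment_hen(frame, 245.0, prefilter=True)
        assert not m.mask[2, 2]
        assert m.mask[9:13, 9:13].all()


class TestFrameMaxHeight:
    def test_subtraction_arithmetic(self):
        frame = np.full((4, 4), 250.0)
        frame[1, 2] = 199.0
        m = wf.segment_hen(frame, 245.0)
        fh = wf.frame_max_height(frame, m, 250.0, frame_index=7)
        assert fh.max_height_cm == pytest.approx(51.0)
        assert fh.peak_pixel == (1, 2)
        assert fh.frame_index == 7

    def test_empty_mask_sets_flag(self):
        frame = np.full((4, 4), 250.0)
        fh = wf.frame_max_height(frame, wf.segment_hen(frame, 245.0), 250.0)
        assert fh.empty and fh.max_height_cm is None and fh.peak_pixel is None

    def test_shape_mismatch_rejected(self):
        frame = np.full((4, 4), 250.0)
        m = wf.segment_hen(np.full((5, 5), 250.0), 245.0)
        with pytest.raises(ValueError):
            wf.frame_max_height(frame, m, 250.0)

    def test_matches_exhaustive_scan_on_random_frames(self):
        # oracle equivalence on >= 100 random frames, exact to machine precision
        rng = np.random.default_rng(7)
        for _ in range(120):
            frame = random_depth_frame(rng)
            thr = rng.uniform(200.0, 249.0)
            m = wf.segment_hen(frame, thr)
            fh = wf.frame_max_height(frame, m, 250.0)
            oracle = brute_force_frame_max(frame, m.mask, 250.0)
            if oracle is None:
                assert fh.empty
            else:
                assert fh.max_height_cm == oracle[0]
                assert fh.peak_pixel == oracle[1]

    def test_tie_breaks_row_major_first(self):
        frame = np.full((4, 4), 250.0)
        frame[2, 1] = frame[1, 3] = 200.0
        fh = wf.frame_max_height(frame, wf.segment_hen(frame, 245.0), 250.0)
        assert fh.peak_pixel == (1, 3)

    def test_monotone_in_pixel_depth(self):
        rng = np.random.default_rng(9)
        frame = random_depth_frame(rng, invalid_fraction=0.0)
        m = wf.segment_hen(frame, 245.0)
        base = wf.frame_max_height(frame, m, 250.0)
        fg = np.argwhere(m.mask)
        r, c = fg[0]
        deeper_up = frame.copy()
        deeper_up[r, c] -= 10.0
        m2 = wf.segment_hen(deeper_up, 245.0)
        assert wf.frame_max_height(deeper_up, m2, 250.0).max_height_cm >= base.max_height_cm
        # adding floor-level pixels changes nothing
        widened = frame.copy()
        widened[frame == 0] = 250.0
        m3 = wf.segment_hen(widened, 245.0)
        assert wf.frame_max_height(widened, m3, 250.0).max_height_cm == base.max_height_cm

    def test_threshold_semantics_invariant(self):
        rng = np.random.default_rng(13)
        for prefilter in (False, True):
            frame = random_depth_frame(rng)
            thr = 245.0
            m = wf.segment_hen(frame, thr, prefilter=prefilter)
            assert not np.any(m.mask & (frame >= thr))
            assert not np.any(m.mask & (frame == wf.INVALID_DEPTH))


class TestBoutReduction:
    def _fh(self, i, h):
        return FrameHeight(i, h, (0, 0), 1, False)

    def test_max_with_argmax_frame(self):
        heights = [self._fh(0, 40.1), self._fh(1, 51.0), self._fh(2, 47.2)]
        bout = wf.bout_max_height(heights, "hen_01")
        assert bout.max_height_cm == 51.0
        assert bout.frame_index == 1
        assert bout.n_frames == 3 and bout.n_nonempty == 3

    def test_tie_takes_earliest_frame(self):
        heights = [self._fh(0, 51.0), self._fh(1, 51.0)]
        assert wf.bout_max_height(heights, "h").frame_index == 0

    def test_all_empty_is_an_error(self):
        heights = [FrameHeight.empty_frame(0), FrameHeight.empty_frame(1)]
        with pytest.raises(ValueError, match="threshold"):
            wf.bout_max_height(heights, "hen_09")

    def test_two_stage_equals_global_reduction(self, small_rig, short_flap):
        b = wf.generate_sequence(short_flap, small_rig)
        thr = wf.floor_threshold(250.0, 5.0)
        fh = wf.extract_frame_heights(b.depth_frames, thr, 250.0)
        bout = wf.bout_max_height(fh, "h")
        masked = [f[(f > 0) & (f < thr)] for f in b.depth_frames]
        global_min = min(m.min() for m in masked if m.size)
        assert bout.max_height_cm == pytest.approx(250.0 - global_min)


class TestOverlay:
    def test_empty_mask_no_peak_returns_unmodified_copy(self):
        img = np.full((10, 10, 3), 7, dtype=np.uint8)
        m = wf.segment_hen(np.full((10, 10), 250.0), 245.0)
        out = wf.render_overlay(img, m, None)
        assert np.array_equal(out, img) and out is not img

    def test_red_disc_at_peak(self):
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        m = wf.segment_hen(np.full((50, 50), 250.0), 245.0)
        out = wf.render_overlay(img, m, (10, 20))
        assert tuple(out[10, 20]) == (255, 0, 0)
        assert tuple(out[10, 20 + 3]) == (255, 0, 0)
        assert tuple(out[10, 20 + 6]) == (0, 0, 0)
        assert np.all(img == 0)    # original untouched

    def test_peak_outside_image_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        m = wf.segment_hen(np.full((10, 10), 250.0), 245.0)
        with pytest.raises(ValueError, match="outside"):
            wf.render_overlay(img, m, (99, 0))

    def test_overlay_per_paired_frame_counts(self, small_rig):
        cfg = wf.FlapConfig(duration=0.3, noise_sigma=0.0, dropout_rate=0.0)
        b = wf.generate_sequence(cfg, small_rig)
        pairs = wf.pair_streams(b.depth_timestamps, b.rgb_timestamps)
        reg = wf.ground_truth_registration(small_rig)
        thr = wf.floor_threshold(250.0, 5.0)
        overlays = []
        for p in pairs:
            rgb = wf.register_rgb(b.rgb_frames[p.rgb_index], reg,
                                  small_rig.depth_resolution)
            frame = b.depth_frames[p.depth_index]
            m = wf.segment_hen(frame, thr)
            fh = wf.frame_max_height(frame, m, 250.0, p.depth_index)
            overlays.append(wf.render_overlay(rgb, m, fh.peak_pixel))
        assert len(overlays) == len(pairs) == b.n_rgb
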