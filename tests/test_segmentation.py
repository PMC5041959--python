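"""Segmentation: local background, nuclei, puncta, skeleton scoring and
line scans, checked against rendered ground truth and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage

from emtscreen.segmentation import (
    CalibrationError,
    FiberNetworkResult,
    InputError,
    MicrographSet,
    SegmentationParams,
    calibrate_thresholds,
    detect_puncta,
    estimate_local_background,
    line_scan_sb_ratio,
    quantify_fiber_network,
    segment_nuclei,
    skeleton_graph_counts,
)
from emtscreen.simulate import ImagingParams, render_well_images

PX = 0.645  # um/px used throughout


def _mset(**channels):
    return MicrographSet(channels=channels, pixel_size=PX)


def _blank(shape=(256, 256), level=100.0):
    return np.full(shape, level)


# -- brute-force skeleton oracle ------------------------------------------


def oracle_skeleton_counts(mask, pixel_size=1.0, fiber_range=None):
    """Independent pure-python reimplementation of the skeleton-graph
    decomposition: per-pixel neighbor counting over coordinate sets and
    hand-rolled flood fill for clustering."""
    pts = {tuple(p) for p in np.argwhere(np.asarray(mask, dtype=bool))}

    def neighbors(p):
        y, x = p
        return [(y + dy, x + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0) and (y + dy, x + dx) in pts]

    junction = {p for p in pts if len(neighbors(p)) >= 3}
    endpoint = {p for p in pts if len(neighbors(p)) == 1}

    def clusters(subset):
        remaining = set(subset)
        out = 0
        while remaining:
            stack = [remaining.pop()]
            while stack:
                p = stack.pop()
                for q in list(remaining):
                    if max(abs(q[0] - p[0]), abs(q[1] - p[1])) <= 1:
                        remaining.remove(q)
                        stack.append(q)
            out += 1
        return out

    n_branch = clusters(junction)
    n_nodes = clusters(endpoint)

    # path components: skeleton minus junction pixels
    remaining = pts - junction
    n_segments = 0
    while remaining:
        comp = {remaining.pop()}
        stack = list(comp)
        while stack:
            p = stack.pop()
            for q in list(remaining):
                if max(abs(q[0] - p[0]), abs(q[1] - p[1])) <= 1:
                    remaining.remove(q)
                    comp.add(q)
                    stack.append(q)
        length = max(len(comp) - 1, 1) * pixel_size
        if fiber_range is None or fiber_range[0] <= length <= fiber_range[1]:
            n_segments += 1
    return n_segments, n_branch, n_nodes


def _random_masks(n=40, shape=(32, 32), density=0.08, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield rng.random(shape) < density


class TestSkeletonGraph:
    def test_empty_mask_scores_zero(self):
        res = skeleton_graph_counts(np.zeros((16, 16), dtype=bool))
        assert (res.segments, res.branch_points, res.nodes) == (0, 0, 0)
        assert res.total_score == 0

    def test_straight_fiber(self):
        # one straight ~3 um fiber: S=1, B=0, N=2, total 3
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 5:10] = True   # 5 px -> (5-1)*0.645 = 2.58 um
        res = skeleton_graph_counts(mask, PX, (1.0, 5.0))
        assert (res.segments, res.branch_points, res.nodes) == (1, 0, 2)
        assert res.total_score == 3

    def test_y_shaped_skeleton(self):
        # three arms meeting at one junction: S=3, B=1, N=3, total 7
        mask = np.zeros((24, 24), dtype=bool)
        mask[12, 6:12] = True           # left arm
        for i in range(1, 7):
            mask[12 - i, 12 + i] = True  # upper-right arm
            mask[12 + i, 12 + i] = True  # lower-right arm
        mask[12, 12] = True
        res = skeleton_graph_counts(mask, PX, (1.0, 8.0))
        assert (res.segments, res.branch_points, res.nodes) == (3, 1, 3)
        assert res.total_score == 7

    def test_matches_brute_force_oracle_on_random_masks(self):
        for mask in _random_masks():
            res = skeleton_graph_counts(mask, PX, (0.1, 50.0))
            expected = oracle_skeleton_counts(mask, PX, (0.1, 50.0))
            assert (res.segments, res.branch_points, res.nodes) == expected

    def test_segment_size_window_is_closed(self):
        # path length exactly at the window bounds is kept
        mask = np.zeros((16, 64), dtype=bool)
        mask[8, 4:9] = True
        length = 4 * 1.0
        res = skeleton_graph_counts(mask, 1.0, (length, length))
        assert res.segments == 1


class TestLocalBackground:
    def test_constant_image_recovered(self):
        img = _blank(level=137.0)
        bg = estimate_local_background(img, 30.0, PX)
        np.testing.assert_allclose(bg, 137.0)

    def test_punctum_removed_matches_median_oracle(self):
        img = _blank(level=200.0)
        img[100:103, 100:103] = 4000.0  # ~2 um punctum
        bg = estimate_local_background(img, 30.0, PX)
        med = ndimage.median_filter(img, size=2 * int(30.0 / PX) + 1,
                                    mode="nearest")
        assert bg[101, 101] == pytest.approx(med[101, 101], abs=1.0)
        assert bg[101, 101] == pytest.approx(200.0, abs=1.0)

    def test_linear_ramp_residual_small(self):
        ramp = np.tile(np.linspace(100.0, 1100.0, 256), (256, 1))
        bg = estimate_local_background(ramp, 10.0, PX)
        residual = ramp - bg
        assert abs(residual.mean()) < 0.01 * 1000.0

    def test_subpixel_radius_rejected(self):
        with pytest.raises(InputError):
            estimate_local_background(_blank(), 0.3, PX)


class TestNuclei:
    def test_blank_image_yields_zero(self):
        res = segment_nuclei(_mset(DAPI=_blank()))
        assert res.count == 0

    def test_rendered_nuclei_counted_exactly(self):
        (mset, truth), = render_well_images(
            20, 0.0, 0.0, 0.0, ImagingParams(),
            rng=np.random.default_rng(2))
        res = segment_nuclei(mset)
        assert res.count == truth["nuclei"] == 20
        assert np.all(res.equivalent_diameters >= 9.0)
        assert np.all(res.equivalent_diameters <= 16.0)

    def test_object_below_size_window_excluded(self):
        img = _blank()
        rr = 2.5 / PX / 2  # 2.5 um disk, below the 9 um window
        yy, xx = np.ogrid[:256, :256]
        img[(yy - 128) ** 2 + (xx - 128) ** 2 <= rr ** 2] = 4000.0
        assert segment_nuclei(_mset(DAPI=img)).count == 0

    def test_missing_channel_raises(self):
        with pytest.raises(InputError):
            segment_nuclei(_mset(FITC=_blank()))

    def test_counts_invariant_under_additive_shift(self):
        (mset, _), = render_well_images(10, 0.0, 0.0, 0.0, ImagingParams(),
                                        rng=np.random.default_rng(4))
        shifted = MicrographSet(
            channels={k: v.astype(float) + 500.0
                      for k, v in mset.channels.items()},
            pixel_size=mset.pixel_size)
        assert segment_nuclei(shifted).count == segment_nuclei(mset).count


class TestPuncta:
    def test_blank_image_yields_zero(self):
        res = detect_puncta(_mset(FITC=_blank()), 10)
        assert res.count == 0 and res.per_cell == 0.0

    def test_rendered_puncta_per_cell_within_5pct(self, rendered_site):
        mset, truth = rendered_site
        nuclei = segment_nuclei(mset)
        res = detect_puncta(mset, nuclei)
        expected = truth["fa_puncta"] / truth["nuclei"]
        assert res.per_cell == pytest.approx(expected, rel=0.05)

    def test_oversized_blob_excluded(self):
        img = _blank()
        rr = 15.0 / PX / 2  # 15 um blob, above the 10 um window
        yy, xx = np.ogrid[:256, :256]
        img[(yy - 128) ** 2 + (xx - 128) ** 2 <= rr ** 2] = 4000.0
        assert detect_puncta(_mset(FITC=img), 5).count == 0

    def test_zero_nuclei_flags_per_cell_undefined(self):
        img = _blank()
        img[100:103, 100:103] = 4000.0
        res = detect_puncta(_mset(FITC=img), 0)
        assert res.count == 1
        assert math.isnan(res.per_cell)


class TestFiberNetworks:
    def test_rendered_fiber_score_close_to_truth(self, rendered_site):
        mset, truth = rendered_site
        nuclei = segment_nuclei(mset)
        res, per_cell = quantify_fiber_network(mset, "TxRed", nuclei)
        expected = 3.0 * truth["sf_fibers"] / truth["nuclei"]
        assert per_cell == pytest.approx(expected, rel=0.15)

    def test_blank_channel_scores_zero(self):
        res, per_cell = quantify_fiber_network(_mset(TxRed=_blank()),
                                               "TxRed", 10)
        assert res.total_score == 0 and per_cell == 0.0

    def test_unit_consistency_under_rescaling(self):
        """Scaling pixel size and structure sizes together leaves the
        per-cell score unchanged."""
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 10:20] = True
        mask[10, 30:40] = True
        fine = skeleton_graph_counts(mask, 0.5, (1.0, 10.0))
        # same mask interpreted at doubled pixel size with doubled window
        coarse = skeleton_graph_counts(mask, 1.0, (2.0, 20.0))
        assert fine.total_score == coarse.total_score


class TestLineScans:
    def test_uniform_image_gives_one(self):
        assert line_scan_sb_ratio([_blank(level=50.0)]) == pytest.approx(1.0)

    def test_plateau_over_background(self):
        img = _blank(level=100.0)
        img[128, 100:150] = 1000.0
        assert line_scan_sb_ratio([img], n_scans=1) == pytest.approx(10.0)

    def test_mean_of_identical_images_equals_single(self):
        img = _blank(level=100.0)
        img[128, 100:150] = 1000.0
        one = line_scan_sb_ratio([img])
        ten = line_scan_sb_ratio([img] * 10)
        assert ten == pytest.approx(one)

    def test_zero_minimum_raises_warning_and_uses_floor(self):
        img = np.zeros((64, 64))
        img[32, 10] = 500.0
        with pytest.warns(UserWarning):
            ratio = line_scan_sb_ratio([img])
        assert ratio == pytest.approx(500.0)


class TestCalibration:
    def _control_wells(self, offset_scale=1.0, n=2, seed=0):
        rng = np.random.default_rng(seed)
        pos, neg = [], []
        for i in range(n):
            (m_neg, _), = render_well_images(6, 30.0, 24.0, 18.0,
                                             ImagingParams(), rng=rng)
            (m_pos, _), = render_well_images(6, 8.0, 6.0, 5.0,
                                             ImagingParams(), rng=rng)
            neg.append([m_neg])
            pos.append([m_pos])
        return pos, neg

    def test_round_trip_recovers_sensible_offsets(self):
        pos, neg = self._control_wells()
        params, achieved = calibrate_thresholds(
            pos, neg, channels=("FITC",), offset_grid=(200.0, 500.0, 2000.0))
        assert params.threshold_offset["FITC"] in (200.0, 500.0, 2000.0)
        assert achieved["FITC"] > 0

    def test_identical_controls_fail_calibration(self):
        img = [_mset(DAPI=_blank(), FITC=_blank(), TxRed=_blank(),
                     Cy5=_blank())]
        with pytest.raises(CalibrationError):
            calibrate_thresholds([img, img], [img, img], channels=("FITC",))

    def test_finer_grid_never_decreases_achieved_zprime(self):
        pos, neg = self._control_wells()
        coarse = (200.0, 2000.0)
        fine = (200.0, 500.0, 1000.0, 2000.0)
        _, z_coarse = calibrate_thresholds(pos, neg, channels=("FITC",),
                                           offset_grid=coarse)
        _, z_fine = calibrate_thresholds(pos, neg, channels=("FITC",),
                                         offset_grid=fine)
        assert z_fine["FITC"] >= z_coarse["FITC"]
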