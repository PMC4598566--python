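"""Unit and property tests for the six-step detection procedure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ciliadyn import ciliaquant, synthdata
from ciliadyn.ciliaquant import (CentrosomeSpot, FieldSummary,
                                 crop_pericentrosomal, detect_centrosomes,
                                 grow_axoneme, measure_axoneme_length,
                                 project_max, quantify_field,
                                 segment_proximal_cluster,
                                 summarize_timecourse)
from ciliadyn.imgio import Config, ImageStack, ParameterError


class TestProjectMax:
    def test_single_plane_identity(self, rng):
        vox = rng.uniform(size=(1, 1, 5, 6))
        stack = ImageStack(vox, 0.5)
        np.testing.assert_array_equal(project_max(stack, 0), vox[0, 0])

    def test_all_zero(self):
        stack = ImageStack(np.zeros((1, 3, 4, 4)), 0.5)
        assert project_max(stack, 0).max() == 0

    @given(hnp.arrays(np.float64, (3, 4, 4),
                      elements=st.floats(0, 100, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_z_loop(self, vol):
        stack = ImageStack(vol[None], 1.0)
        out = project_max(stack, 0)
        for y in range(4):
            for x in range(4):
                expect = max(vol[z, y, x] for z in range(3))
                assert out[y, x] == expect

    def test_bad_channel(self):
        stack = ImageStack(np.zeros((1, 1, 4, 4)), 0.5)
        with pytest.raises(ParameterError):
            project_max(stack, 2)


class TestDetectCentrosomes:
    def test_flat_image_no_spots(self):
        assert detect_centrosomes(np.full((64, 64), 10.0)) == []

    def test_single_spot_recovered_within_1px(self):
        img = synthdata.render_spot_image(np.array([[30.0, 22.0]]), (64, 64), 100.0)
        # oracle: intensity argmax of the noiseless render
        oy, ox = np.unravel_index(img.argmax(), img.shape)
        spots = detect_centrosomes(img)
        assert len(spots) == 1
        assert abs(spots[0].position[0] - ox) <= 1
        assert abs(spots[0].position[1] - oy) <= 1

    def test_two_spots_separated(self):
        img = synthdata.render_spot_image(
            np.array([[20.0, 32.0], [40.0, 32.0]]), (64, 64), 100.0)
        spots = detect_centrosomes(img, min_separation_px=5.0)
        assert len(spots) == 2
        xs = sorted(s.position[0] for s in spots)
        assert abs(xs[0] - 20) <= 1 and abs(xs[1] - 40) <= 1

    def test_close_spots_keep_brighter(self):
        img = (synthdata.render_spot_image(np.array([[30.0, 30.0]]), (64, 64), 200.0)
               + synthdata.render_spot_image(np.array([[33.0, 30.0]]), (64, 64), 80.0))
        spots = detect_centrosomes(img, min_separation_px=8.0)
        assert len(spots) == 1
        assert abs(spots[0].position[0] - 30) <= 1


class TestCrop:
    def test_crop_side_forced_odd(self):
        img = np.zeros((100, 100))
        crop, _, _ = crop_pericentrosomal(img, CentrosomeSpot((50, 50), 1.0),
                                          pixel_size_um=0.5, crop_side_um=11.0)
        assert crop.shape == (23, 23)  # round(22) even -> 23

    def test_corner_spot_padded_and_flagged(self):
        img = np.arange(100.0).reshape(10, 10)
        crop, origin, padded = crop_pericentrosomal(
            img, CentrosomeSpot((0, 0), 1.0), pixel_size_um=1.0, crop_side_um=7.0)
        assert padded
        assert crop.shape == (7, 7)
        # padded area carries the image background median
        assert crop[0, 0] == np.median(img)

    def test_interior_spot_center_pixel_matches(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(50, 50))
        crop, _, padded = crop_pericentrosomal(
            img, CentrosomeSpot((25, 30), 1.0), pixel_size_um=1.0, crop_side_um=9.0)
        assert not padded
        assert crop[crop.shape[0] // 2, crop.shape[1] // 2] == img[30, 25]

    def test_tiny_crop_rejected(self):
        with pytest.raises(ParameterError):
            crop_pericentrosomal(np.zeros((10, 10)), CentrosomeSpot((5, 5), 1.0),
                                 pixel_size_um=10.0, crop_side_um=11.0)


def _bruteforce_components(binary):
    """Flood-fill oracle: 8-connected components of a boolean image."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for y, x in zip(*np.nonzero(binary)):
        if seen[y, x]:
            continue
        stack, comp = [(y, x)], set()
        seen[y, x] = True
        while stack:
            cy, cx = stack.pop()
            comp.add((cy, cx))
            for dy, dx in itertools.product((-1, 0, 1), repeat=2):
                ny, nx = cy + dy, cx + dx
                if (0 <= ny < binary.shape[0] and 0 <= nx < binary.shape[1]
                        and binary[ny, nx] and not seen[ny, nx]):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        comps.append(comp)
    return comps


class TestSegmentProximalCluster:
    def test_central_blob_equals_threshold_oracle(self, rng):
        crop = rng.uniform(0, 1, size=(21, 21))
        crop[8:13, 8:13] += 10.0
        mask = segment_proximal_cluster(crop, seed_quantile=0.9, min_seed_px=4)
        thresh = np.quantile(crop, 0.9)
        comps = _bruteforce_components(crop > thresh)
        # oracle: nearest-to-center component with area >= 4
        cy = cx = 10.0
        best = min((c for c in comps if len(c) >= 4),
                   key=lambda c: min(np.hypot(y - cy, x - cx) for y, x in c))
        assert set(zip(*np.nonzero(mask))) == best

    def test_constant_crop_empty(self):
        assert not segment_proximal_cluster(np.full((15, 15), 3.0)).any()

    def test_center_blob_beats_corner_blob(self):
        crop = np.zeros((21, 21))
        crop[9:12, 9:12] = 10.0
        crop[0:4, 0:4] = 10.0
        mask = segment_proximal_cluster(crop, seed_quantile=0.5, min_seed_px=4)
        assert mask[10, 10] and not mask[1, 1]


class TestGrowAxoneme:
    def test_noiseless_filament_iou(self):
        # crisp filament on a flat background: growth should recover it
        poly = np.array([[10.0, 22.0], [34.0, 22.0]])
        truth_mask = synthdata._render_polyline_mask(poly, (45, 45))
        # quantile below the filament's area fraction so the threshold sits
        # in the background plateau of this two-valued image
        crop = truth_mask * 100.0 + 10.0
        seed = segment_proximal_cluster(crop, seed_quantile=0.95, min_seed_px=4)
        mask = grow_axoneme(crop, seed, contrast_stop_ratio=1.5)
        inter = (mask & truth_mask).sum()
        union = (mask | truth_mask).sum()
        assert inter / union >= 0.8

    def test_flat_crop_no_growth(self):
        crop = np.full((15, 15), 5.0)
        seed = np.zeros((15, 15), dtype=bool)
        seed[7, 7] = True
        np.testing.assert_array_equal(grow_axoneme(crop, seed), seed)

    def test_zero_iterations_returns_seed(self, rng):
        crop = rng.uniform(0, 100, size=(15, 15))
        seed = np.zeros((15, 15), dtype=bool)
        seed[7, 7] = True
        np.testing.assert_array_equal(
            grow_axoneme(crop, seed, max_iterations=0), seed)

    def test_empty_seed_returned_empty(self):
        crop = np.ones((9, 9))
        seed = np.zeros((9, 9), dtype=bool)
        assert not grow_axoneme(crop, seed).any()

    def test_result_is_superset_of_seed(self, rng):
        crop = rng.uniform(0, 100, size=(21, 21))
        seed = np.zeros((21, 21), dtype=bool)
        seed[10, 10] = seed[10, 11] = True
        mask = grow_axoneme(crop, seed)
        assert (mask | seed).sum() == mask.sum()


def _bruteforce_longest_path(skel):
    """Exhaustive simple-path enumeration on a tiny skeleton pixel graph."""
    pixels = list(zip(*np.nonzero(skel)))
    adj = {p: [] for p in pixels}
    for (y, x) in pixels:
        for dy, dx in itertools.product((-1, 0, 1), repeat=2):
            if (dy, dx) != (0, 0) and (y + dy, x + dx) in adj:
                adj[(y, x)].append(((y + dy, x + dx),
                                    np.sqrt(2.0) if dy and dx else 1.0))
    best = 0.0
    # longest *geodesic* (shortest-path) distance between any pixel pair,
    # by Dijkstra-free exhaustive relaxation on <= 25 pixels
    import heapq
    for src in pixels:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        best = max(best, max(dist.values()))
    return best


class TestMeasureLength:
    def test_horizontal_run(self):
        mask = np.zeros((5, 15), dtype=bool)
        mask[2, 2:13] = True  # 11 pixels
        assert measure_axoneme_length(mask, 0.5) == pytest.approx(5.0)

    def test_empty_mask_zero(self):
        assert measure_axoneme_length(np.zeros((5, 5), dtype=bool), 0.5) == 0.0

    def test_l_shape_matches_exhaustive_search(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[2, 2:12] = True   # 10 right
        mask[2:12, 11] = True  # 10 down
        from skimage.morphology import skeletonize
        skel = skeletonize(mask)
        assert skel.sum() <= 25
        expect = _bruteforce_longest_path(skel)
        assert measure_axoneme_length(mask, 1.0) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_masks_match_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((8, 8), dtype=bool)
        y, x = 4, 1
        mask[y, x] = True
        for _ in range(12):
            dy, dx = rng.integers(-1, 2, size=2)
            y, x = np.clip(y + dy, 0, 7), np.clip(x + dx, 0, 7)
            mask[y, x] = True
        from skimage.morphology import skeletonize
        skel = skeletonize(mask)
        if skel.sum() < 2 or skel.sum() > 25:
            pytest.skip("degenerate draw")
        expect = _bruteforce_longest_path(skel)
        assert measure_axoneme_length(mask, 1.0) == pytest.approx(expect)


class TestQuantifyField:
    def test_zero_fraction_zero_percent(self):
        params = synthdata.FieldParams(field_size_px=(384, 384), n_centrosomes=12,
                                       ciliation_fraction=0.0, n_z=4)
        stack, _ = synthdata.generate_cilia_field(params, seed=3)
        _, summary = quantify_field(stack)
        assert summary.percent_ciliated == 0.0

    def test_recovers_fraction_and_length(self, small_field):
        params, stack, truth = small_field
        records, summary = quantify_field(stack)
        assert abs(summary.percent_ciliated - 100 * truth.ciliated_fraction) <= 10
        true_mean = np.mean([c.true_length_um for c in truth.centrosomes
                             if c.ciliated])
        assert summary.mean_length_um == pytest.approx(true_mean, abs=0.7)

    def test_percent_invariant_to_intensity_scaling(self, small_field):
        # quantile/ratio thresholds make the call scale-invariant (a*I, a>0)
        _, stack, _ = small_field
        _, s1 = quantify_field(stack)
        scaled = ImageStack(stack.voxels * 3.7, stack.pixel_size_um,
                            list(stack.channel_names))
        _, s2 = quantify_field(scaled)
        assert s1.percent_ciliated == s2.percent_ciliated

    def test_blank_stack_flagged_invalid(self):
        stack = ImageStack(np.full((2, 3, 64, 64), 5.0), 0.25)
        _, summary = quantify_field(stack)
        assert summary.n_cells == 0 and not summary.valid


class TestTimecourse:
    @staticmethod
    def _fs(cond, tp, pct, fid="f"):
        return FieldSummary(condition=cond, timepoint_h=tp, n_cells=100,
                            percent_ciliated=pct, mean_length_um=3.0,
                            sd_length_um=0.5, field_id=fid)

    def test_identical_groups_t0_p1(self):
        fields = ([self._fs("ctl", 0, p) for p in (70, 72, 71)]
                  + [self._fs("kd", 0, p) for p in (70, 72, 71)])
        points, tests = summarize_timecourse(fields, control="ctl")
        assert tests["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tests["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self):
        a, b = [10.0, 12.0, 11.0], [20.0, 22.0, 21.0]
        fields = ([self._fs("kd", 0, v) for v in a]
                  + [self._fs("ctl", 0, v) for v in b])
        _, tests = summarize_timecourse(fields, control="ctl")
        # independent textbook computation
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t_expect = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        from scipy.stats import t as tdist
        p_expect = 2 * tdist.sf(abs(t_expect), df)
        assert tests["t"].iloc[0] == pytest.approx(t_expect)
        assert tests["p"].iloc[0] == pytest.approx(p_expect)

    def test_single_replicate_sem_missing_test_skipped(self):
        fields = [self._fs("ctl", 0, 70), self._fs("kd", 0, 50)]
        with pytest.warns(UserWarning):
            points, tests = summarize_timecourse(fields, control="ctl")
        assert all(np.isnan(p.sem_percent_ciliated) for p in points)
        assert np.isnan(tests["p"].iloc[0])

    def test_unknown_control_rejected(self):
        with pytest.raises(ParameterError):
            summarize_timecourse([self._fs("ctl", 0, 70)], control="nope")

    def test_sem_is_sd_over_sqrt_n(self):
        vals = [60.0, 70.0, 80.0, 66.0]
        fields = [self._fs("ctl", 2.0, v) for v in vals]
        points, _ = summarize_timecourse(fields, control="ctl")
        expect = np.std(vals, ddof=1) / 2.0
        assert points[0].sem_percent_ciliated == pytest.approx(expect)
        assert points[0].n_replicates == 4
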