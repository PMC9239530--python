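"""Point/contour matching, Hausdorff distance and segmentation summaries."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Polygon

from wsirs.detection import (
    detection_scores,
    equivalent_diameter,
    hausdorff_distance,
    match_contours,
    match_points,
    polygon_iou,
    reference_detector,
    seg_summary,
)
from wsirs.records import CellRecord
from wsirs.synthetic import (
    SceneConfig,
    SceneGroundTruth,
    gen_scene,
    perturb_detections,
    render_scene,
)


def _square(x, y, side=1.0):
    return np.array([[x, y], [x + side, y], [x + side, y + side], [x, y + side]])


def _separated_points(rng, n, spacing=60.0, span=600.0):
    """Random points pairwise at least ``spacing`` apart (rejection)."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, span, size=2)
        if all(np.hypot(*(p - q)) >= spacing for q in pts):
            pts.append(p)
    return np.array(pts)


def _exhaustive_point_match(gt, pred, radius):
    """Independent oracle: maximize matched pairs, then minimize total
    distance, over all injective gt->pred assignments."""
    best = (0, 0.0)
    n_g, n_p = len(gt), len(pred)
    k = min(n_g, n_p)
    best_count, best_dist = -1, np.inf
    for gt_subset in itertools.combinations(range(n_g), k):
        for perm in itertools.permutations(range(n_p), k):
            count, dist = 0, 0.0
            for gi, pi in zip(gt_subset, perm):
                d = np.hypot(*(gt[gi] - pred[pi]))
                if d <= radius:
                    count += 1
                    dist += d
            if count > best_count or (count == best_count and dist < best_dist):
                best_count, best_dist = count, dist
    return best_count


class TestMatchPoints:
    def test_identity_sets_match_perfectly(self, rng):
        pts = rng.uniform(0, 100, size=(12, 2))
        res = match_points(pts, pts, radius=1.0)
        assert (res.tp, res.fp, res.fn) == (12, 0, 0)

    def test_far_apart_points_do_not_match(self):
        res = match_points(np.array([[0.0, 0.0]]), np.array([[100.0, 100.0]]),
                           radius=12)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_counting_identities_hold(self, rng):
        gt = rng.uniform(0, 200, size=(15, 2))
        pred = rng.uniform(0, 200, size=(11, 2))
        res = match_points(gt, pred, radius=20)
        assert res.tp == len(res.pairs)
        assert res.tp + res.fn == 15
        assert res.tp + res.fp == 11

    def test_agrees_with_exhaustive_assignment_on_perturbed_sets(self):
        # well-separated points with small jitter: the spec's instance family
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gt = _separated_points(rng, 6)
            pred = gt + rng.normal(0, 2.0, size=gt.shape)
            res = match_points(gt, pred, radius=12)
            assert res.tp == _exhaustive_point_match(gt, pred, radius=12)

    def test_accepts_cell_records(self):
        gt = [CellRecord("tumor", 10, 10), CellRecord("til", 50, 50)]
        res = match_points(gt, gt, radius=1)
        assert res.tp == 2

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            match_points([], [], radius=0)


class TestDetectionScores:
    def test_recall_from_raw_counts(self):
        assert detection_scores(6101, 0, 7609 - 6101)["recall"] == pytest.approx(
            0.8018, abs=5e-5)
        assert detection_scores(3304, 0, 696)["recall"] == pytest.approx(
            0.826, abs=5e-4)

    def test_f1_equals_p_when_p_equals_r(self):
        s = detection_scores(10, 5, 5)
        assert s["precision"] == s["recall"] == s["f1"]

    def test_f1_between_min_and_max(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, size=3)
            s = detection_scores(int(tp), int(fp), int(fn))
            assert min(s["precision"], s["recall"]) <= s["f1"] + 1e-12
            assert s["f1"] <= max(s["precision"], s["recall"]) + 1e-12

    def test_undefined_denominators_rejected(self):
        with pytest.raises(ValueError):
            detection_scores(0, 0, 5)
        with pytest.raises(ValueError):
            detection_scores(0, 5, 0)


class TestPolygonIou:
    def test_identical_squares(self):
        sq = _square(0, 0)
        assert polygon_iou(sq, sq) == pytest.approx(1.0)

    def test_disjoint_squares(self):
        assert polygon_iou(_square(0, 0), _square(5, 5)) == 0.0

    def test_half_overlap_is_one_third(self):
        assert polygon_iou(_square(0, 0), _square(0.5, 0)) == pytest.approx(1 / 3)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            a = _square(*rng.uniform(0, 3, 2), side=rng.uniform(0.5, 2))
            b = _square(*rng.uniform(0, 3, 2), side=rng.uniform(0.5, 2))
            iou_ab, iou_ba = polygon_iou(a, b), polygon_iou(b, a)
            assert iou_ab == pytest.approx(iou_ba, abs=1e-12)
            assert 0.0 <= iou_ab <= 1.0

    def test_degenerate_polygon_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            polygon_iou(line, _square(0, 0))


def _sequential_rule_oracle(gt, pred, cutoff):
    """Naive re-simulation of the published matching rule, kept separate
    from the implementation: scan ground truths in order, give each the
    highest-IOU free prediction at or above the cutoff."""
    taken = {}
    for gi in range(len(gt)):
        ranked = []
        for pi in range(len(pred)):
            if pi in taken.values():
                continue
            pa, pb = Polygon(gt[gi]), Polygon(pred[pi])
            iou = pa.intersection(pb).area / pa.union(pb).area
            if iou >= cutoff:
                ranked.append((iou, -pi))
        if ranked:
            iou, neg_pi = max(ranked)
            taken[gi] = -neg_pi
    return {(gi, pi) for gi, pi in taken.items()}


class TestMatchContours:
    def test_largest_iou_retained(self):
        gt = [_square(0, 0)]
        pred = [_square(0.2, 0), _square(0.6, 0)]  # IOUs ~0.67 and ~0.25
        res = match_contours(gt, pred, cutoff=0.2)
        assert res.pairs[0][:2] == (0, 0)

    def test_first_ground_truth_keeps_shared_prediction(self):
        gt = [_square(0, 0), _square(0.1, 0)]
        pred = [_square(0.05, 0)]
        res = match_contours(gt, pred, cutoff=0.5)
        assert res.pairs == [(0, 0, pytest.approx(polygon_iou(gt[0], pred[0])))]
        assert res.unmatched_gt == [1]

    def test_matches_sequential_rule_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n_g, n_p = rng.integers(1, 5), rng.integers(1, 5)
            gt = [_square(*rng.uniform(0, 3, 2), side=1.0) for _ in range(n_g)]
            pred = [_square(*rng.uniform(0, 3, 2), side=1.0) for _ in range(n_p)]
            res = match_contours(gt, pred, cutoff=0.1)
            assert {(gi, pi) for gi, pi, _ in res.pairs} == \
                _sequential_rule_oracle(gt, pred, 0.1)

    def test_higher_cutoff_pairs_are_admissible_at_lower(self):
        rng = np.random.default_rng(4)
        gt = [_square(*rng.uniform(0, 4, 2)) for _ in range(4)]
        pred = [_square(*rng.uniform(0, 4, 2)) for _ in range(4)]
        strict = match_contours(gt, pred, cutoff=0.5)
        assert all(iou >= 0.5 for _, _, iou in strict.pairs)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            match_contours([], [], cutoff=1.5)


class TestHausdorff:
    def test_identical_polygons_zero(self):
        sq = _square(0, 0, side=10)
        assert hausdorff_distance(sq, sq) == 0.0

    def test_single_points_euclidean(self):
        assert hausdorff_distance(np.array([[0.0, 0.0]]),
                                  np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_translated_congruent_squares(self):
        sq = _square(0, 0, side=10)
        assert hausdorff_distance(sq, sq + [3.7, 0]) == pytest.approx(3.7, abs=0.1)

    def test_symmetric(self, rng):
        a = _square(*rng.uniform(0, 5, 2), side=3)
        b = _square(*rng.uniform(0, 5, 2), side=4)
        assert hausdorff_distance(a, b) == pytest.approx(
            hausdorff_distance(b, a), abs=1e-9)

    def test_triangle_inequality_within_densification_slack(self, rng):
        for _ in range(10):
            a = _square(*rng.uniform(0, 8, 2), side=rng.uniform(2, 5))
            b = _square(*rng.uniform(0, 8, 2), side=rng.uniform(2, 5))
            c = _square(*rng.uniform(0, 8, 2), side=rng.uniform(2, 5))
            assert hausdorff_distance(a, c) <= (
                hausdorff_distance(a, b) + hausdorff_distance(b, c) + 2.0)


class TestEquivalentDiameter:
    def test_unit_radius_circle(self):
        assert equivalent_diameter(np.pi) == pytest.approx(2.0)

    def test_area_100(self):
        assert equivalent_diameter(100.0) == pytest.approx(11.2838, abs=1e-4)

    def test_sqrt2_scaling(self):
        assert equivalent_diameter(200.0) == pytest.approx(
            np.sqrt(2) * equivalent_diameter(100.0))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)


class TestSegSummary:
    def _gt_scene(self):
        rng = np.random.default_rng(8)
        gt, grades, areas = [], [], []
        for i in range(12):
            side = rng.uniform(18, 40)
            sq = _square(60.0 * i, 0.0, side=side)
            gt.append(sq)
            areas.append(side**2)
            grades.append(1 + i % 3)
        return gt, grades, areas

    def test_perfect_predictions_have_zero_hd(self):
        gt, grades, areas = self._gt_scene()
        summary = seg_summary(gt, gt, grades, areas, cutoffs=[0.3, 0.7])
        matched = summary.dropna(subset=["mean_hd"])
        assert (matched["mean_hd"] == 0.0).all()
        assert (matched["ratio_pct"] == 0.0).all()

    def test_single_matched_pair_summary(self):
        gt = [_square(0, 0, side=20)]
        pred = [_square(2, 0, side=20)]
        summary = seg_summary(gt, pred, [2], [400.0], cutoffs=[0.5])
        row = summary.iloc[0]
        assert row["n_pairs"] == 1
        assert row["mean_hd"] == pytest.approx(
            hausdorff_distance(gt[0], pred[0]))
        assert row["mean_equiv_diameter"] == pytest.approx(
            equivalent_diameter(400.0))

    def test_mean_hd_non_decreasing_as_cutoff_loosens(self):
        gt, grades, areas = self._gt_scene()
        rng = np.random.default_rng(9)
        pred = [sq + rng.uniform(-6, 6, size=2) for sq in gt]
        summary = seg_summary(gt, pred, grades, areas,
                              cutoffs=[0.1, 0.3, 0.5, 0.7])
        pooled = (summary.dropna(subset=["mean_hd"])
                  .groupby("cutoff")
                  .apply(lambda d: np.average(d["mean_hd"], weights=d["n_pairs"]),
                         include_groups=False))
        assert all(a >= b - 1e-9 for a, b in zip(pooled.values, pooled.values[1:]))


class TestReferenceDetector:
    def test_detects_well_separated_synthetic_nuclei(self):
        cfg = SceneConfig(canvas_width=1024, canvas_height=1024,
                          n_tumor_clusters=0, til_density_background=0)
        base = gen_scene(cfg)
        rng = np.random.default_rng(3)
        cells = []
        for i in range(5):
            from wsirs.synthetic import _ellipse_contour

            x, y = 150.0 + 150 * i, 300.0
            contour = _ellipse_contour(rng, x, y, 4.0 * 304.7)
            cells.append(CellRecord("tumor", x, y, contour=contour, grade=3))
        for i in range(5):
            cells.append(CellRecord("til", 150.0 + 150 * i, 700.0))
        scene = SceneGroundTruth(cells=cells, canvas_width=1024, canvas_height=1024)
        detected = reference_detector(render_scene(scene))
        res = match_points(scene.cells, detected, radius=12)
        assert res.tp == 10 and res.fp == 0 and res.fn == 0
        classes = {(round(c.x), round(c.y)): c.cell_class for c in detected}
        for cell in scene.cells:
            gi_pi = [p for p in res.pairs if scene.cells[p[0]] is cell]
            assert detected[gi_pi[0][1]].cell_class == cell.cell_class


class TestPerturbationRoundTrip:
    def test_known_rates_recovered_within_binomial_error(self):
        cfg = SceneConfig(canvas_width=2048, canvas_height=2048,
                          n_tumor_clusters=4, tumor_cells_per_cluster_mean=120,
                          til_density_background=60, seed=21)
        scene = gen_scene(cfg)
        n = len(scene.cells)
        fn, fp = 0.2, 0.25
        recalls, precisions = [], []
        for seed in range(40):
            pred = perturb_detections(scene, fn, fp, jitter_sd=1.0, seed=seed)
            res = match_points(scene.cells, pred, radius=6)
            s = detection_scores(res.tp, res.fp, res.fn)
            recalls.append(s["recall"])
            precisions.append(s["precision"])
        sd_r = np.sqrt(fn * (1 - fn) / n)
        assert abs(np.mean(recalls) - (1 - fn)) < 3 * sd_r
        # expected precision ~ (1-fn) / (1-fn+fp) when FPs rarely match
        expect_p = (1 - fn) / (1 - fn + fp)
        assert abs(np.mean(precisions) - expect_p) < 0.05
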