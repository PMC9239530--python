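"""Detection and segmentation evaluation against ground truth.

Point detections are scored by greedy nearest-first matching within a
radius, yielding TP/FP/FN and precision/recall/F1. Nucleus contours are
matched by IOU at a cutoff K with sequential tie-breaking (largest IOU
per ground truth; a prediction stays with the first ground truth it was
assigned to), then summarized by the Hausdorff distance of matched pairs
and the per-grade mean equivalent diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff
from shapely.geometry import Polygon

from .records import TIL, TUMOR, CellRecord

DEFAULT_MATCH_RADIUS = 12.0  # px, about half the grade-1 equivalent diameter


@dataclass(frozen=True)
class PointMatchResult:
    """Greedy point-matching outcome.

    Invariants: TP = len(pairs), TP + FN = |gt|, TP + FP = |pred|.
    """

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (gt_idx, pred_idx, distance px)


def match_points(gt: Sequence, pred: Sequence,
                 radius: float = DEFAULT_MATCH_RADIUS) -> PointMatchResult:
    """Greedy nearest-first one-to-one matching within ``radius``.

    Candidate pairs within the radius are sorted by ascending distance
    (ties by (gt_idx, pred_idx)) and accepted when both endpoints are
    still unused. Unmatched ground truths are FN, unmatched predictions
    FP.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    gt_xy = _points_array(gt)
    pred_xy = _points_array(pred)
    candidates = []
    if len(gt_xy) and len(pred_xy):
        tree = cKDTree(pred_xy)
        for gi, neighbors in enumerate(tree.query_ball_point(gt_xy, r=radius)):
            for pi in neighbors:
                d = float(np.hypot(*(gt_xy[gi] - pred_xy[pi])))
                candidates.append((d, gi, pi))
    candidates.sort()
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs = []
    for d, gi, pi in candidates:
        if gi in used_gt or pi in used_pred:
            continue
        used_gt.add(gi)
        used_pred.add(pi)
        pairs.append((gi, pi, d))
    tp = len(pairs)
    return PointMatchResult(tp=tp, fp=len(pred_xy) - tp, fn=len(gt_xy) - tp,
                            pairs=pairs)


def _points_array(items: Sequence) -> np.ndarray:
    if len(items) == 0:
        return np.empty((0, 2))
    if isinstance(items[0], CellRecord):
        return np.array([[c.x, c.y] for c in items], dtype=float)
    return np.asarray(items, dtype=float).reshape(len(items), 2)


def detection_scores(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R)."""
    if tp + fp == 0:
        raise ValueError("precision undefined: no predictions")
    if tp + fn == 0:
        raise ValueError("recall undefined: no ground truths")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else (
        2 * precision * recall / (precision + recall))
    return {"precision": precision, "recall": recall, "f1": f1}


def _as_polygon(p) -> Polygon:
    poly = p if isinstance(p, Polygon) else Polygon(np.asarray(p, dtype=float))
    if poly.area == 0:
        raise ValueError("degenerate (zero-area) polygon")
    return poly


def polygon_iou(a, b) -> float:
    """Intersection over union of two simple polygons (exact clipping)."""
    pa, pb = _as_polygon(a), _as_polygon(b)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class ContourMatchSet:
    """IOU-cutoff contour matching outcome at cutoff K."""

    cutoff: float
    pairs: list[tuple[int, int, float]]  # (gt_idx, pred_idx, iou)
    unmatched_gt: list[int]
    unmatched_pred: list[int]


def match_contours(gt: Sequence, pred: Sequence, cutoff: float) -> ContourMatchSet:
    """Match ground-truth to predicted contours at IOU cutoff K.

    Ground truths are scanned in index order. Each takes the available
    prediction with the largest IOU >= K (IOU ties break toward the
    lower prediction index); a prediction already assigned to an earlier
    ground truth stays with it.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("IOU cutoff must lie in [0, 1]")
    gt_polys = [_as_polygon(g) for g in gt]
    pred_polys = [_as_polygon(p) for p in pred]
    assigned: set[int] = set()
    pairs = []
    for gi, g in enumerate(gt_polys):
        best = None  # (iou, pred_idx)
        for pi, p in enumerate(pred_polys):
            if pi in assigned:
                continue
            iou = polygon_iou(g, p)
            if iou >= cutoff and (best is None or iou > best[0]):
                best = (iou, pi)
        if best is not None:
            assigned.add(best[1])
            pairs.append((gi, best[1], best[0]))
    matched_gt = {gi for gi, _, _ in pairs}
    return ContourMatchSet(
        cutoff=cutoff,
        pairs=pairs,
        unmatched_gt=[i for i in range(len(gt_polys)) if i not in matched_gt],
        unmatched_pred=[i for i in range(len(pred_polys)) if i not in assigned],
    )


def hausdorff_distance(a, b, max_segment: float = 1.0) -> float:
    """Symmetric Hausdorff distance between boundaries, in pixels.

    Polygon boundaries are densified to segments of at most
    ``max_segment`` px before the point-set Hausdorff distance is taken,
    bounding the discretization error by half a segment. Plain point
    arrays are accepted as-is (degenerate "boundaries").
    """
    pa, pb = _boundary_points(a, max_segment), _boundary_points(b, max_segment)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def _boundary_points(obj, max_segment: float) -> np.ndarray:
    if isinstance(obj, Polygon):
        poly = obj
    else:
        arr = np.asarray(obj, dtype=float).reshape(-1, 2)
        if len(arr) < 3:
            return arr
        poly = Polygon(arr)
    if poly.area == 0:
        raise ValueError("degenerate polygon")
    dense = poly.segmentize(max_segment)
    return np.asarray(dense.exterior.coords, dtype=float)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: sqrt(4*area/pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(4.0 * area / math.pi)


def seg_summary(
    gt: Sequence,
    pred: Sequence,
    gt_grades: Sequence[int],
    gt_areas: Sequence[float],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
) -> pd.DataFrame:
    """Grade-stratified segmentation summary over IOU cutoffs.

    For each cutoff K and grade g: the mean Hausdorff distance over
    matched pairs whose ground truth has grade g, the mean equivalent
    diameter over *all* ground-truth nuclei of grade g, and their ratio
    in percent. Strata without matches carry NaN mean HD.
    """
    if len(gt) != len(gt_grades) or len(gt) != len(gt_areas):
        raise ValueError("gt, gt_grades and gt_areas must align")
    grades = np.asarray(gt_grades, dtype=int)
    diam_by_grade = {
        g: float(np.mean([equivalent_diameter(a)
                          for a, gg in zip(gt_areas, grades) if gg == g]))
        for g in sorted(set(grades.tolist()))
    }
    hd_cache: dict[tuple[int, int], float] = {}
    rows = []
    for k in cutoffs:
        matches = match_contours(gt, pred, cutoff=float(k))
        for g, mean_diam in diam_by_grade.items():
            hds = []
            for gi, pi, _ in matches.pairs:
                if grades[gi] != g:
                    continue
                if (gi, pi) not in hd_cache:
                    hd_cache[(gi, pi)] = hausdorff_distance(gt[gi], pred[pi])
                hds.append(hd_cache[(gi, pi)])
            mean_hd = float(np.mean(hds)) if hds else float("nan")
            rows.append({
                "cutoff": float(k), "grade": int(g), "n_pairs": len(hds),
                "mean_hd": mean_hd, "mean_equiv_diameter": mean_diam,
                "ratio_pct": mean_hd / mean_diam * 100.0,
            })
    return pd.DataFrame(rows)


def reference_detector(raster: np.ndarray,
                       til_ref_area: float = 304.7,
                       dark_value_max: float = 180.0,
                       min_area: float = 60.0) -> list[CellRecord]:
    """Simple color/size blob detector for synthetic rasters.

    Nuclei rendered as dark blobs on a pale background are segmented by
    thresholding the HSV value channel, labeled, and classified tumor vs
    TIL by mean red channel (the synthetic renderer draws the two
    classes in distinct colors). Intended as a deterministic stand-in
    detector for exercising the evaluation machinery on rendered scenes.
    """
    from skimage.measure import label, regionprops

    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError("expected an RGB raster")
    value = raster.max(axis=2).astype(float)
    nuclei = value < dark_value_max
    out = []
    for region in regionprops(label(nuclei), intensity_image=raster[..., 0]):
        if region.area < min_area:
            continue
        y, x = region.centroid
        cls = TUMOR if region.intensity_mean > 70 else TIL
        out.append(CellRecord(cls, float(x), float(y), area=float(region.area)))
    return out
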