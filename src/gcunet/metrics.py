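"""Instance-level segmentation metrics: AJI, Dice, and Panoptic Quality.

Conventions (documented and asserted in the tests):

* An *instance map* is an integer array, 0 = background, k >= 1 = instance id.
* AJI: ground-truth instances are visited in ascending id order; each picks
  the not-yet-used prediction with the highest IoU (ties broken by the
  lowest prediction id; zero-IoU means no match and contributes |G_i| to
  the denominator). Unused predictions add their areas to the denominator.
* PQ: a (prediction, ground-truth) pair matches iff IoU > 0.5; above that
  threshold the matching is provably unique. RQ = TP/(TP + FP/2 + FN/2),
  SQ = mean matched IoU (0 if there are no matches), PQ = SQ * RQ.
* Degenerate cases: Dice of two empty masks is 1.0; PQ of two empty
  instance maps is 1.0 (TP=FP=FN=0); AJI of two empty maps is 1.0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, iou)
    unmatched_gt: list[int]
    unmatched_pred: list[int]


@dataclass
class MetricReport:
    aji: float
    dice: float
    pq: float
    sq: float
    rq: float
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _overlap_matrix(gt: np.ndarray, pred: np.ndarray):
    """Pixel-count contingency table including the background row/column."""
    gt = np.ascontiguousarray(gt, dtype=np.int64)
    pred = np.ascontiguousarray(pred, dtype=np.int64)
    ng, npred = int(gt.max()), int(pred.max())
    table = np.bincount(gt.ravel() * (npred + 1) + pred.ravel(),
                        minlength=(ng + 1) * (npred + 1))
    return table.reshape(ng + 1, npred + 1), ng, npred


def extract_instances(prob: np.ndarray, threshold: float = 0.5,
                      min_size: int = 10, connectivity: int = 4) -> np.ndarray:
    """Threshold a probability map and label connected components.

    Components smaller than ``min_size`` pixels are dropped; surviving ids
    are renumbered 1..K in raster-scan order of each component's first pixel.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if connectivity == 4
                 else np.ones((3, 3), dtype=int))
    binary = np.asarray(prob) >= threshold
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels.astype(np.int32)
    if min_size > 0:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        small = np.flatnonzero(counts < min_size)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return relabel_sequential(labels)


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Renumber positive ids 1..K by raster order of first occurrence."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    fg = flat > 0
    if not fg.any():
        return np.zeros_like(labels, dtype=np.int32)
    ids, first = np.unique(flat[fg], return_index=True)
    order = np.argsort(first)
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    lut[ids[order]] = np.arange(1, ids.size + 1)
    return lut[labels]


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard Index with used-prediction bookkeeping."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    _check_shapes(gt, pred)
    table, ng, npred = _overlap_matrix(gt, pred)
    gt_ids = np.flatnonzero(np.bincount(gt.ravel(), minlength=ng + 1)[1:]) + 1
    pred_areas = np.bincount(pred.ravel(), minlength=npred + 1)
    pred_ids = np.flatnonzero(pred_areas[1:]) + 1
    if gt_ids.size == 0 and pred_ids.size == 0:
        return 1.0
    gt_areas = np.bincount(gt.ravel(), minlength=ng + 1)
    used = set()
    num = 0
    den = 0
    for g in gt_ids:
        inter = table[g, 1:]
        best_j, best_iou, best_i = 0, 0.0, 0
        for j in pred_ids:
            if j in used or inter[j - 1] == 0:
                continue
            i = int(inter[j - 1])
            union = int(gt_areas[g]) + int(pred_areas[j]) - i
            iou = i / union
            if iou > best_iou:  # ties keep the lowest prediction id
                best_j, best_iou, best_i = j, iou, i
        if best_j == 0:
            den += int(gt_areas[g])
        else:
            union = int(gt_areas[g]) + int(pred_areas[best_j]) - best_i
            num += best_i
            den += union
            used.add(best_j)
    for j in pred_ids:
        if j not in used:
            den += int(pred_areas[j])
    return num / den if den else 1.0


def dice(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """2|G n P| / (|G| + |P|); two empty masks score 1.0."""
    gt_mask = np.asarray(gt_mask).astype(bool)
    pred_mask = np.asarray(pred_mask).astype(bool)
    _check_shapes(gt_mask, pred_mask)
    total = int(gt_mask.sum()) + int(pred_mask.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((gt_mask & pred_mask).sum()) / total


def match_instances(gt: np.ndarray, pred: np.ndarray,
                    iou_threshold: float = 0.5) -> MatchResult:
    """Unique matching of instances with IoU strictly above the threshold."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    _check_shapes(gt, pred)
    table, ng, npred = _overlap_matrix(gt, pred)
    gt_areas = np.bincount(gt.ravel(), minlength=ng + 1)
    pred_areas = np.bincount(pred.ravel(), minlength=npred + 1)
    gt_ids = [g for g in range(1, ng + 1) if gt_areas[g] > 0]
    pred_ids = [p for p in range(1, npred + 1) if pred_areas[p] > 0]
    pairs = []
    matched_gt, matched_pred = set(), set()
    for g in gt_ids:
        for p in pred_ids:
            inter = int(table[g, p])
            if inter == 0:
                continue
            iou = inter / (int(gt_areas[g]) + int(pred_areas[p]) - inter)
            if iou > iou_threshold:
                pairs.append((g, p, iou))
                matched_gt.add(g)
                matched_pred.add(p)
    return MatchResult(
        pairs=pairs,
        unmatched_gt=[g for g in gt_ids if g not in matched_gt],
        unmatched_pred=[p for p in pred_ids if p not in matched_pred],
    )


def panoptic_quality(gt: np.ndarray, pred: np.ndarray) -> MetricReport:
    """PQ/SQ/RQ under IoU > 0.5 matching, with AJI and binary Dice attached."""
    match = match_instances(gt, pred, 0.5)
    tp = len(match.pairs)
    fp = len(match.unmatched_pred)
    fn = len(match.unmatched_gt)
    if tp + fp + fn == 0:
        sq = rq = 1.0  # both maps empty: perfect by convention
    else:
        rq = tp / (tp + 0.5 * fp + 0.5 * fn)
        sq = float(np.mean([iou for _, _, iou in match.pairs])) if tp else 0.0
    return MetricReport(
        aji=aji(gt, pred),
        dice=dice(np.asarray(gt) > 0, np.asarray(pred) > 0),
        pq=sq * rq, sq=sq, rq=rq, tp=tp, fp=fp, fn=fn,
    )


def evaluate_pair(gt: np.ndarray, prob: np.ndarray, threshold: float = 0.5,
                  min_size: int = 10, connectivity: int = 4) -> MetricReport:
    """Instance-extract a probability map and score it against ground truth."""
    gt = np.asarray(gt)
    prob = np.asarray(prob)
    _check_shapes(gt, prob)
    pred = extract_instances(prob, threshold=threshold, min_size=min_size,
                             connectivity=connectivity)
    return panoptic_quality(gt, pred)


# -- directory-level evaluation (CLI backend) ------------------------------


def _load_label_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int64)


def evaluate_dirs(gt_dir, pred_dir, threshold: float = 0.5, min_size: int = 10,
                  out_path=None) -> dict:
    """Score matching instance-map files from two directories.

    Files are matched on their numeric/stem suffix (``inst_0003`` in the gt
    directory pairs with ``inst_0003``/``pred_0003``/``0003`` in the other).
    Writes JSON (and a CSV next to it) when ``out_path`` is given.
    """
    gt_dir, pred_dir = Path(gt_dir), Path(pred_dir)

    def stem_key(p: Path) -> str:
        s = p.stem
        changed = True
        while changed:
            changed = False
            for prefix in ("inst_", "pred_", "mask_", "image_"):
                if s.startswith(prefix):
                    s = s[len(prefix):]
                    changed = True
        return s

    exts = {".png", ".tif", ".tiff"}
    gt_files = {stem_key(p): p for p in sorted(gt_dir.iterdir())
                if p.suffix.lower() in exts and not p.name.startswith(("image_", "prob_"))}
    pred_files = {stem_key(p): p for p in sorted(pred_dir.iterdir())
                  if p.suffix.lower() in exts and not p.name.startswith(("image_", "prob_", "mask_"))}
    missing = sorted(set(gt_files) - set(pred_files))
    if missing:
        raise FileNotFoundError(
            f"no prediction found in {pred_dir} for ground-truth stems: {missing}")
    rows = []
    for key in sorted(gt_files):
        gt = _load_label_image(gt_files[key])
        pred = _load_label_image(pred_files[key])
        if pred.max() <= 1:  # binary mask or probability-coded file
            pred = extract_instances(pred.astype(float), threshold=threshold,
                                     min_size=min_size)
        report = panoptic_quality(gt, pred)
        rows.append({"image": key, **report.to_dict()})
    metric_keys = ["aji", "dice", "pq", "sq", "rq", "tp", "fp", "fn"]
    mean_row = {k: float(np.mean([r[k] for r in rows])) for k in metric_keys}
    result = {"per_image": rows, "mean": mean_row, "n_images": len(rows),
              "threshold": threshold, "min_size": min_size}
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(json.dumps(result, indent=2))
        csv_path = out_path.with_suffix(".csv")
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image"] + metric_keys)
            writer.writeheader()
            for r in rows:
                writer.writerow(r)
            writer.writerow({"image": "mean", **{k: mean_row[k] for k in metric_keys}})
    return result
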