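"""Metric correctness: hand-derived worked cases, an independent
pixel-set double-loop oracle, and fuzzed invariants."""

import numpy as np
import pytest

from gcunet.metrics import (MatchResult, aji, dice, evaluate_pair,
                            extract_instances, match_instances,
                            panoptic_quality, relabel_sequential)
from conftest import random_instance_map


# -- independent oracle (pixel sets, explicit double loops) ----------------


def _pixel_sets(labels):
    out = {}
    for idx, v in np.ndenumerate(labels):
        if v > 0:
            out.setdefault(int(v), set()).add(idx)
    return out


def oracle_aji(gt, pred):
    G, P = _pixel_sets(gt), _pixel_sets(pred)
    if not G and not P:
        return 1.0
    used, num, den = set(), 0, 0
    for g in sorted(G):
        best, best_iou = None, 0.0
        for p in sorted(P):
            if p in used:
                continue
            inter = len(G[g] & P[p])
            if inter == 0:
                continue
            iou = inter / len(G[g] | P[p])
            if iou > best_iou:
                best, best_iou = p, iou
        if best is None:
            den += len(G[g])
        else:
            num += len(G[g] & P[best])
            den += len(G[g] | P[best])
            used.add(best)
    for p in sorted(P):
        if p not in used:
            den += len(P[p])
    return num / den if den else 1.0


def oracle_dice(gt_mask, pred_mask):
    G = {idx for idx, v in np.ndenumerate(gt_mask) if v}
    P = {idx for idx, v in np.ndenumerate(pred_mask) if v}
    if not G and not P:
        return 1.0
    return 2 * len(G & P) / (len(G) + len(P))


def oracle_pq(gt, pred):
    G, P = _pixel_sets(gt), _pixel_sets(pred)
    pairs = []
    for g in sorted(G):
        for p in sorted(P):
            inter = len(G[g] & P[p])
            if inter and inter / len(G[g] | P[p]) > 0.5:
                pairs.append((g, p, inter / len(G[g] | P[p])))
    tp = len(pairs)
    fp = len(P) - len({p for _, p, _ in pairs})
    fn = len(G) - len({g for g, _, _ in pairs})
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0, 0, 0, 0
    rq = tp / (tp + 0.5 * fp + 0.5 * fn)
    sq = sum(iou for _, _, iou in pairs) / tp if tp else 0.0
    return sq * rq, sq, rq, tp, fp, fn


# -- worked examples -------------------------------------------------------


def test_aji_hand_derived_half():
    gt = np.zeros((4, 4), dtype=int)
    gt[0, 0] = gt[0, 1] = 1
    gt[3, 3] = 2
    pred = np.zeros((4, 4), dtype=int)
    pred[0, 0] = pred[0, 1] = 1
    pred[2, 2] = 2
    # G1 matches P1 exactly (2/2); G2 has no intersecting prediction (+1);
    # P2 is unused (+1): AJI = 2 / (2 + 1 + 1)
    assert aji(gt, pred) == pytest.approx(0.5)
    assert oracle_aji(gt, pred) == pytest.approx(0.5)


def test_pq_hand_derived_half():
    gt = np.zeros((8, 8), dtype=int)
    gt[0:3, 0:3] = 1
    gt[5:8, 5:8] = 2
    pred = np.zeros((8, 8), dtype=int)
    pred[0:3, 0:3] = 1    # exact reproduction of gt 1
    pred[5:7, 0:2] = 2    # spurious blob
    report = panoptic_quality(gt, pred)
    assert (report.tp, report.fp, report.fn) == (1, 1, 1)
    assert report.sq == pytest.approx(1.0)
    assert report.rq == pytest.approx(0.5)
    assert report.pq == pytest.approx(0.5)


def test_dice_worked_case():
    gt = np.zeros((4, 4), dtype=bool)
    gt[0, 0:4] = True                      # |G| = 4
    pred = np.zeros((4, 4), dtype=bool)
    pred[0, 1:4] = True                    # overlap 3
    pred[1, 0:3] = True                    # |P| = 6
    assert dice(gt, pred) == pytest.approx(0.6)


def test_perfect_and_empty_conventions(instance_map_factory):
    gt = instance_map_factory(n_blobs=(2, 4))
    assert aji(gt, gt) == pytest.approx(1.0)
    report = panoptic_quality(gt, gt)
    assert report.pq == pytest.approx(1.0)
    assert dice(gt > 0, gt > 0) == pytest.approx(1.0)

    empty = np.zeros_like(gt)
    if gt.max() > 0:
        assert aji(gt, empty) == 0.0
        assert dice(gt > 0, empty > 0) == 0.0
    assert dice(empty > 0, empty > 0) == 1.0
    r = panoptic_quality(empty, empty)
    assert (r.pq, r.tp, r.fp, r.fn) == (1.0, 0, 0, 0)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape mismatch"):
        aji(np.zeros((3, 3), int), np.zeros((4, 4), int))
    with pytest.raises(ValueError, match="shape mismatch"):
        dice(np.zeros((3, 3), bool), np.zeros((4, 3), bool))


# -- oracle fuzzing --------------------------------------------------------


def test_metrics_match_oracle_on_100_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        gt = random_instance_map(rng, shape=(16, 16))
        pred = random_instance_map(rng, shape=(16, 16))
        assert aji(gt, pred) == oracle_aji(gt, pred)
        assert dice(gt > 0, pred > 0) == oracle_dice(gt > 0, pred > 0)
        report = panoptic_quality(gt, pred)
        pq_o, sq_o, rq_o, tp_o, fp_o, fn_o = oracle_pq(gt, pred)
        assert report.pq == pytest.approx(pq_o, abs=1e-12)
        assert report.sq == pytest.approx(sq_o, abs=1e-12)
        assert report.rq == pytest.approx(rq_o, abs=1e-12)
        assert (report.tp, report.fp, report.fn) == (tp_o, fp_o, fn_o)


def test_bounds_and_uniqueness_fuzz():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        gt = random_instance_map(rng, shape=(12, 12), n_blobs=(0, 4))
        pred = random_instance_map(rng, shape=(12, 12), n_blobs=(0, 4))
        a = aji(gt, pred)
        d = dice(gt > 0, pred > 0)
        report = panoptic_quality(gt, pred)
        for v in (a, d, report.pq, report.sq, report.rq):
            assert 0.0 <= v <= 1.0
        assert report.pq == pytest.approx(report.sq * report.rq, abs=1e-9)
        # above IoU 0.5 the matching is necessarily one-to-one
        match = match_instances(gt, pred)
        gts = [g for g, _, _ in match.pairs]
        preds = [p for _, p, _ in match.pairs]
        assert len(gts) == len(set(gts)) and len(preds) == len(set(preds))


def test_erosion_strictly_decreases_dice():
    from scipy.ndimage import binary_erosion

    mask = np.zeros((20, 20), dtype=bool)
    mask[4:16, 5:15] = True
    eroded = binary_erosion(mask)
    assert dice(mask, mask) == 1.0
    assert dice(mask, eroded) < 1.0


# -- instance extraction ---------------------------------------------------


def test_extract_two_blobs():
    prob = np.zeros((10, 10))
    prob[1:3, 1:3] = 0.9
    prob[6:9, 6:9] = 0.8
    inst = extract_instances(prob, threshold=0.5, min_size=1)
    assert inst.max() == 2
    assert inst[1, 1] == 1 and inst[7, 7] == 2  # raster-scan id order


def test_extract_empty_map():
    inst = extract_instances(np.zeros((8, 8)), threshold=0.5, min_size=1)
    assert inst.max() == 0


def test_extract_min_size_filter():
    prob = np.zeros((20, 20))
    prob[0:10, 0:10] = 1.0  # 100-pixel blob
    assert extract_instances(prob, 0.5, min_size=150).max() == 0
    assert extract_instances(prob, 0.5, min_size=100).max() == 1


def test_extract_connectivity_matters():
    prob = np.zeros((4, 4))
    prob[0, 0] = prob[1, 1] = 1.0  # diagonal touch
    assert extract_instances(prob, 0.5, 0, connectivity=4).max() == 2
    assert extract_instances(prob, 0.5, 0, connectivity=8).max() == 1


def test_relabel_sequential_raster_order():
    labels = np.array([[0, 7, 7], [300, 0, 7], [300, 300, 0]])
    out = relabel_sequential(labels)
    assert out[0, 1] == 1 and out[1, 0] == 2


# -- evaluate_pair ---------------------------------------------------------


def test_evaluate_pair_perfect_indicator():
    gt = np.zeros((16, 16), dtype=int)
    gt[2:6, 2:6] = 1
    gt[9:14, 9:14] = 2
    prob = (gt > 0).astype(float)
    report = evaluate_pair(gt, prob, threshold=0.5, min_size=1)
    assert report.aji == report.dice == report.pq == 1.0


def test_evaluate_pair_all_background():
    gt = np.zeros((16, 16), dtype=int)
    gt[2:6, 2:6] = 1
    gt[9:14, 9:14] = 2
    report = evaluate_pair(gt, np.zeros((16, 16)), threshold=0.5, min_size=1)
    assert report.aji == 0.0 and report.dice == 0.0
    assert report.fn == 2 and report.tp == 0


def test_evaluate_pair_matches_oracle_fuzz():
    rng = np.random.default_rng(11)
    for _ in range(100):
        gt = random_instance_map(rng, shape=(16, 16))
        prob = rng.random((16, 16))
        report = evaluate_pair(gt, prob, threshold=0.6, min_size=2)
        pred = extract_instances(prob, threshold=0.6, min_size=2)
        assert report.aji == oracle_aji(gt, pred)
        pq_o = oracle_pq(gt, pred)[0]
        assert report.pq == pytest.approx(pq_o, abs=1e-12)
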