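"""Metric suite: matching, P/R/Dice, AP, PQ against brute-force oracles."""

import itertools
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhcellseg import metrics
from dhcellseg.metrics import (
    MatchTable,
    average_precision,
    evaluate,
    mask_iou,
    match_instances,
    panoptic_quality,
    precision_recall_dice,
)


@dataclass
class Pred:
    mask: np.ndarray
    score: float = 1.0


def block(h, w, r0, r1, c0, c1):
    m = np.zeros((h, w), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def brute_force_match(pred_masks, truth_masks, threshold):
    """Exhaustive optimal assignment: maximize TP, then total IoU."""
    iou = np.array([[mask_iou(p, t) for t in truth_masks] for p in pred_masks])
    best = (0, -1.0, [])
    n_p, n_t = len(pred_masks), len(truth_masks)
    for k in range(min(n_p, n_t), -1, -1):
        for preds in itertools.combinations(range(n_p), k):
            for truths in itertools.permutations(range(n_t), k):
                if all(iou[p, t] > threshold for p, t in zip(preds, truths)):
                    total = sum(iou[p, t] for p, t in zip(preds, truths))
                    if (k, total) > (best[0], best[1]):
                        best = (k, total, list(zip(preds, truths)))
        if best[0] == k and best[0] > 0:
            break
    return best


class TestMaskIoU:
    def test_identical_masks(self):
        m = block(4, 4, 0, 2, 0, 2)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        assert mask_iou(block(4, 4, 0, 2, 0, 2), block(4, 4, 2, 4, 2, 4)) == 0.0

    def test_shifted_block(self):
        a = block(4, 4, 0, 2, 0, 2)
        b = block(4, 4, 0, 2, 1, 3)
        assert mask_iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_zero(self):
        z = np.zeros((3, 3), bool)
        assert mask_iou(z, z) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestMatching:
    def test_no_predictions(self):
        truths = [block(8, 8, 0, 2, 0, 2), block(8, 8, 3, 5, 3, 5),
                  block(8, 8, 6, 8, 6, 8)]
        t = match_instances([], truths)
        assert (t.tp, t.fp, t.fn) == (0, 0, 3)

    def test_perfect_match(self):
        truths = [block(8, 8, 0, 3, 0, 3), block(8, 8, 4, 8, 4, 8)]
        t = match_instances([Pred(m) for m in truths], truths)
        assert (t.tp, t.fp, t.fn) == (2, 0, 0)
        assert all(iou == 1.0 for _, _, iou in t.pairs)

    def test_two_predictions_one_truth(self):
        truth = block(10, 10, 0, 5, 0, 10)  # 50 px
        p_hi = block(10, 10, 0, 5, 0, 9)    # IoU 45/51 ~ 0.88
        p_lo = block(10, 10, 0, 5, 0, 7)    # IoU 35/50 = 0.70
        t = match_instances([Pred(p_hi, 0.9), Pred(p_lo, 0.8)], [truth])
        assert (t.tp, t.fp, t.fn) == (1, 1, 0)
        assert t.pairs[0][0] == 0  # the higher-IoU prediction wins

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_agrees_with_exhaustive_assignment(self, data):
        """Greedy matching equals brute force for <= 6 objects at IoU 0.5."""
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        n_t = data.draw(st.integers(0, 3))
        n_p = data.draw(st.integers(0, 3))
        truths, preds = [], []
        for _ in range(n_t):
            r, c = rng.integers(0, 6, 2)
            truths.append(block(12, 12, r, r + 5, c, c + 5))
        for _ in range(n_p):
            r, c = rng.integers(0, 6, 2)
            preds.append(Pred(block(12, 12, r, r + 5, c, c + 5),
                              float(rng.random())))
        table = match_instances(preds, truths, 0.5)
        k, _, _ = brute_force_match([p.mask for p in preds], truths, 0.5)
        assert table.tp == k

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        truths = [block(16, 16, 0, 5, 0, 5), block(16, 16, 6, 11, 6, 11),
                  block(16, 16, 11, 16, 0, 5)]
        preds = [Pred(m, s) for m, s in zip(truths, (0.9, 0.8, 0.7))]
        base = evaluate(preds, truths)
        for perm in itertools.permutations(range(3)):
            shuffled = [preds[i] for i in perm]
            rep = evaluate(shuffled, truths)
            assert rep.pq == pytest.approx(base.pq)
            assert rep.ap == pytest.approx(base.ap)


class TestPrecisionRecallDice:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (2, 1, 1, (2 / 3, 2 / 3, 2 / 3)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (3, 1, 2, (3 / 4, 3 / 5, 2 / 3)),
        ],
    )
    def test_formulas(self, tp, fp, fn, expected):
        table = MatchTable(
            pairs=[(i, i, 1.0) for i in range(tp)],
            unmatched_predictions=list(range(tp, tp + fp)),
            unmatched_truths=list(range(tp, tp + fn)),
            iou_threshold=0.5,
        )
        p, r, d = precision_recall_dice(table)
        assert (p, r, d) == pytest.approx(expected)

    def test_dice_is_harmonic_mean(self):
        table = MatchTable(pairs=[(0, 0, 0.9)] * 1,
                           unmatched_predictions=[1],
                           unmatched_truths=[1, 2],
                           iou_threshold=0.5)
        p, r, d = precision_recall_dice(table)
        assert d == pytest.approx(2 * p * r / (p + r))


def brute_force_ap(preds, truths, threshold):
    """AP by explicit threshold enumeration + interpolated area."""
    scores = sorted({p.score for p in preds}, reverse=True)
    points = []
    for cut in scores:
        kept = [p for p in preds if p.score >= cut]
        table = match_instances(kept, truths, threshold)
        prec, rec, _ = precision_recall_dice(table)
        points.append((rec, prec))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        p_env = max(p for rr, p in points[i:])
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_single_perfect_prediction(self):
        truth = block(8, 8, 0, 4, 0, 4)
        ap, curve = average_precision([Pred(truth, 0.9)], [truth])
        assert ap == 1.0

    def test_all_misses(self):
        truth = block(8, 8, 0, 4, 0, 4)
        miss = block(8, 8, 5, 8, 5, 8)
        ap, _ = average_precision([Pred(miss, 0.9)], [truth])
        assert ap == 0.0

    def test_hit_miss_hit_sequence(self):
        a = block(16, 16, 0, 5, 0, 5)
        b = block(16, 16, 8, 13, 8, 13)
        miss = block(16, 16, 0, 5, 8, 13)
        preds = [Pred(a, 0.9), Pred(miss, 0.8), Pred(b, 0.7)]
        ap, _ = average_precision(preds, [a, b])
        want = brute_force_ap(preds, [a, b], 0.5)
        assert ap == pytest.approx(want)
        assert ap == pytest.approx(5 / 6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        truths = [block(20, 20, r, r + 6, c, c + 6)
                  for r, c in rng.integers(0, 13, (3, 2))]
        preds = [Pred(block(20, 20, r, r + 6, c, c + 6), float(s))
                 for (r, c), s in zip(rng.integers(0, 13, (4, 2)),
                                      rng.random(4))]
        ap, _ = average_precision(preds, truths)
        assert ap == pytest.approx(brute_force_ap(preds, truths, 0.5))

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        truths = [block(16, 16, 0, 6, 0, 6), block(16, 16, 8, 14, 8, 14)]
        preds = [Pred(truths[0], 0.8), Pred(truths[1], 0.3),
                 Pred(block(16, 16, 0, 6, 8, 14), 0.5)]
        ap1, _ = average_precision(preds, truths)
        squashed = [Pred(p.mask, p.score ** 3 + 1) for p in preds]
        ap2, _ = average_precision(squashed, truths)
        assert ap1 == pytest.approx(ap2)

    def test_empty_inputs(self):
        assert average_precision([], [], 0.5)[0] == 0.0

    def test_coco_style_averaging_mode(self):
        truth = block(8, 8, 0, 4, 0, 4)
        near = block(8, 8, 0, 4, 0, 3)  # IoU 0.75
        cuts = [0.5 + 0.05 * i for i in range(10)]
        ap, _ = average_precision([Pred(near, 0.9)], [truth],
                                  iou_thresholds=cuts)
        # a hit at IoU 0.75 counts for cuts below 0.75 only: 5 of 10
        assert ap == pytest.approx(0.5)


class TestPanopticQuality:
    def test_perfect(self):
        truths = [block(8, 8, 0, 3, 0, 3), block(8, 8, 4, 8, 4, 8)]
        pq, dq, sq = panoptic_quality([Pred(m) for m in truths], truths)
        assert (pq, dq, sq) == (1.0, 1.0, 1.0)

    def test_worked_example_pq_04(self):
        # one match at IoU 0.8, one FP, one FN -> DQ 0.5, SQ 0.8, PQ 0.4
        truth_a = block(20, 20, 0, 5, 0, 10)      # 50 px
        pred_a = block(20, 20, 0, 5, 0, 8)        # inter 40, union 50
        assert mask_iou(pred_a, truth_a) == pytest.approx(0.8)
        truth_b = block(20, 20, 10, 15, 0, 5)     # missed
        pred_fp = block(20, 20, 10, 15, 10, 15)   # spurious
        pq, dq, sq = panoptic_quality(
            [Pred(pred_a, 0.9), Pred(pred_fp, 0.8)], [truth_a, truth_b])
        assert dq == pytest.approx(0.5)
        assert sq == pytest.approx(0.8)
        assert pq == pytest.approx(0.4)

    def test_no_predictions(self):
        truths = [block(8, 8, 0, 3, 0, 3)]
        assert panoptic_quality([], truths) == (0.0, 0.0, 0.0)

    def test_pq_never_exceeds_dq(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            truths = [block(16, 16, r, r + 6, c, c + 6)
                      for r, c in rng.integers(0, 10, (3, 2))]
            preds = [Pred(block(16, 16, r, r + 6, c, c + 6), float(s))
                     for (r, c), s in zip(rng.integers(0, 10, (3, 2)),
                                          rng.random(3))]
            pq, dq, sq = panoptic_quality(preds, truths)
            assert pq <= dq + 1e-12


class TestEvaluateReport:
    def test_report_consistency(self):
        truths = [block(16, 16, 0, 6, 0, 6), block(16, 16, 8, 14, 8, 14)]
        preds = [Pred(truths[0], 0.9), Pred(block(16, 16, 0, 6, 8, 14), 0.4)]
        rep = evaluate(preds, truths)
        assert rep.pq == pytest.approx(rep.dq * rep.sq, abs=1e-12)
        for v in (rep.precision, rep.recall, rep.dice, rep.ap, rep.pq):
            assert 0.0 <= v <= 1.0

    def test_pixel_dice_differs_from_count_dice(self):
        truth = block(10, 10, 0, 5, 0, 10)
        near = block(10, 10, 0, 5, 0, 9)
        rep = evaluate([Pred(near, 0.9)], [truth])
        assert rep.dice == 1.0                      # count-based: 1 TP only
        assert rep.dice_pixel == pytest.approx(2 * 45 / (45 + 50))

    def test_report_io(self, tmp_path):
        truth = block(8, 8, 0, 4, 0, 4)
        rep = evaluate([Pred(truth, 1.0)], [truth])
        rep.to_json(tmp_path / "m.json")
        rep.to_tsv(tmp_path / "m.tsv")
        import json
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded["pq"] == pytest.approx(rep.dq * rep.sq)
        assert (tmp_path / "m.tsv").read_text().startswith("precision\t")
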