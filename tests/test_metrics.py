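"""Evaluation suite vs brute-force per-pixel and per-boundary-pixel oracles."""

import numpy as np
import pytest

from myinet.metrics import (ConfusionMatrix, bf_precision_recall, bfscore,
                            boundary_map, class_iou, confusion_matrix,
                            dataset_bfscore, default_boundary_tolerance,
                            global_accuracy, image_bfscore, mean_accuracy,
                            per_image_report, weighted_iou)


def brute_confusion(g, p, n):
    out = np.zeros((n, n), dtype=int)
    for a, b in zip(g.ravel(), p.ravel()):
        out[a, b] += 1
    return out


def brute_boundary(mask):
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def brute_pr(bp, bg, tol):
    bp_pts = np.argwhere(bp)
    bg_pts = np.argwhere(bg)
    if len(bp_pts):
        d = (np.min(np.linalg.norm(bp_pts[:, None] - bg_pts[None], axis=-1), axis=1)
             if len(bg_pts) else np.full(len(bp_pts), np.inf))
        precision = float(np.mean(d < tol))
    else:
        precision = 0.0
    if len(bg_pts):
        d = (np.min(np.linalg.norm(bg_pts[:, None] - bp_pts[None], axis=-1), axis=1)
             if len(bp_pts) else np.full(len(bg_pts), np.inf))
        recall = float(np.mean(d < tol))
    else:
        recall = 0.0
    return precision, recall


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        g = rng.integers(0, 4, (16, 16))
        cm = confusion_matrix(g, g)
        assert np.all(cm.counts[~np.eye(4, dtype=bool)] == 0)

    def test_hand_counted_example(self):
        g = np.array([[0, 0, 1, 1]])
        p = np.array([[0, 1, 1, 1]])
        cm = confusion_matrix(g, p, n_classes=2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_total_conservation_and_marginals(self, rng):
        g, p = rng.integers(0, 4, (2, 12, 12))
        cm = confusion_matrix(g, p)
        assert cm.total == g.size
        assert cm.true_totals.sum() == cm.pred_totals.sum() == g.size

    def test_shape_mismatch_identifies_image(self):
        with pytest.raises(ValueError, match="image 1"):
            confusion_matrix([np.zeros((2, 2), int)] * 2,
                             [np.zeros((2, 2), int), np.zeros((3, 3), int)])


class TestAggregateAccuracies:
    def test_hand_arithmetic(self):
        cm = ConfusionMatrix(np.array([[1, 1], [0, 2]]))
        assert global_accuracy(cm) == pytest.approx(0.75)
        assert mean_accuracy(cm) == pytest.approx(0.75)

    def test_mean_accuracy_reproduces_published_row(self):
        # per-class accuracies of the 18-layer residual variant; their
        # unweighted mean must reproduce the published aggregate 0.8483
        acc = np.array([0.7441, 0.8255, 0.8511, 0.9724])
        m = 10_000
        counts = np.diag(np.round(acc * m).astype(int))
        for a in range(4):
            counts[a, (a + 1) % 4] += m - counts[a, a]
        value = mean_accuracy(ConfusionMatrix(counts))
        assert round(value, 4) == 0.8483

    def test_mean_accuracy_skips_absent_class(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 8
        counts[1, 1] = 2
        counts[1, 0] = 2
        assert mean_accuracy(ConfusionMatrix(counts)) == pytest.approx((1 + 0.5) / 2)

    def test_class_iou_overlapping_disks(self):
        # two 100-pixel masks overlapping in 60 pixels: IoU = 60/140
        g = np.zeros(200, int)
        p = np.zeros(200, int)
        g[:100] = 1
        p[40:140] = 1
        cm = confusion_matrix(g.reshape(10, 20), p.reshape(10, 20), 2)
        assert class_iou(cm, 1) == pytest.approx(60 / 140)

    def test_weighted_iou_weights_by_true_share(self):
        counts = np.array([[90, 0], [10, 0]])
        cm = ConfusionMatrix(counts)
        # class 0: IoU = 90/100; class 1: IoU = 0
        assert weighted_iou(cm) == pytest.approx(0.9 * 0.9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            global_accuracy(ConfusionMatrix(np.zeros((2, 2), int)))


class TestMetricOracles:
    def test_aggregates_match_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            g, p = rng.integers(0, 4, (2, 32, 32))
            cm = confusion_matrix(g, p)
            ref = brute_confusion(g, p, 4)
            np.testing.assert_array_equal(cm.counts, ref)
            assert global_accuracy(cm) == pytest.approx((g == p).mean(), abs=1e-12)
            wiou_ref = sum(
                (ref[a].sum() / ref.sum())
                * ref[a, a] / (ref[a].sum() + ref[:, a].sum() - ref[a, a])
                for a in range(4) if ref[a].sum())
            assert weighted_iou(cm) == pytest.approx(wiou_ref, abs=1e-12)
            for a in range(4):
                iou = class_iou(cm, a)
                acc = ref[a, a] / ref[a].sum() if ref[a].sum() else np.nan
                if not np.isnan(iou) and not np.isnan(acc):
                    assert iou <= acc + 1e-12

    def test_boundary_map_matches_neighbour_scan(self, rng):
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.4
            np.testing.assert_array_equal(boundary_map(mask), brute_boundary(mask))

    def test_boundary_map_edge_cases(self):
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        np.testing.assert_array_equal(boundary_map(single), single)
        full = np.ones((5, 5), bool)
        frame = np.ones((5, 5), bool)
        frame[1:-1, 1:-1] = False
        np.testing.assert_array_equal(boundary_map(full), frame)
        assert not boundary_map(np.zeros((4, 4), bool)).any()


class TestBoundaryF1:
    def test_identical_boundaries_score_one(self, rng):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        b = boundary_map(mask)
        assert bf_precision_recall(b, b, 1.0) == (1.0, 1.0)

    def test_distant_points_score_zero(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[2, 2] = True
        b[2, 12] = True
        assert bf_precision_recall(a, b, 2.7) == (0.0, 0.0)

    def test_one_pixel_shift_within_tolerance(self):
        g = np.zeros((16, 16), int)
        p = np.zeros((16, 16), int)
        g[4:10, 4:10] = 1
        p[5:11, 4:10] = 1
        assert bfscore(g, p, 1, tol=1.5) == pytest.approx(1.0)

    def test_default_tolerance_is_fraction_of_diagonal(self):
        tol = default_boundary_tolerance((256, 256))
        assert tol == pytest.approx(0.0075 * np.sqrt(2 * 256 ** 2))
        assert tol == pytest.approx(2.715, abs=5e-3)

    def test_harmonic_mean_formula(self):
        # P=1, R=0.5 -> F1 = 2/3; realised with a half-covered boundary
        p_, r_ = 1.0, 0.5
        assert 2 * p_ * r_ / (p_ + r_) == pytest.approx(2 / 3)

    def test_precision_recall_match_brute_force(self, rng):
        for _ in range(10):
            g = rng.integers(0, 2, (20, 20))
            p = rng.integers(0, 2, (20, 20))
            bg, bp = boundary_map(g == 1), boundary_map(p == 1)
            for tol in (1.0, 2.5):
                ours = bf_precision_recall(bp, bg, tol)
                ref = brute_pr(bp, bg, tol)
                assert ours == pytest.approx(ref, abs=1e-9)

    def test_symmetry_swapping_gt_and_pred(self, rng):
        g = rng.integers(0, 3, (24, 24))
        p = rng.integers(0, 3, (24, 24))
        for o in range(3):
            assert bfscore(g, p, o) == pytest.approx(bfscore(p, g, o), abs=1e-12)

    def test_monotone_in_tolerance(self, rng):
        g = rng.integers(0, 2, (24, 24))
        p = rng.integers(0, 2, (24, 24))
        scores = [bfscore(g, p, 1, tol) for tol in (0.5, 1.5, 3.0, 6.0)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_dataset_score_is_mean_of_image_scores(self, rng):
        pairs = [(rng.integers(0, 4, (16, 16)), rng.integers(0, 4, (16, 16)))
                 for _ in range(6)]
        per_image = [image_bfscore(g, p) for g, p in pairs]
        assert dataset_bfscore(pairs) == pytest.approx(np.mean(per_image))


class TestPerImageReport:
    def test_perfect_prediction_rows(self, rng):
        g = rng.integers(0, 4, (16, 16))
        table = per_image_report([(g, g)])
        row = table.iloc[0]
        assert row.global_accuracy == 1.0
        assert row.lge_true_positives == row.lge_predicted_positives

    def test_no_lge_anywhere_gives_zero_counts(self):
        g = np.zeros((8, 8), int)
        table = per_image_report([(g, g)])
        assert table.iloc[0].lge_true_positives == 0
        assert table.iloc[0].lge_predicted_positives == 0

    def test_rows_match_single_image_metrics(self, rng):
        pairs = [(rng.integers(0, 4, (16, 16)), rng.integers(0, 4, (16, 16)))
                 for _ in range(4)]
        table = per_image_report(pairs)
        for row, (g, p) in zip(table.itertuples(), pairs):
            cm = confusion_matrix(g, p)
            assert row.global_accuracy == pytest.approx(global_accuracy(cm))
            assert row.mean_accuracy == pytest.approx(mean_accuracy(cm))
            assert row.bfscore == pytest.approx(image_bfscore(g, p))
            assert row.lge_true_positives <= row.lge_predicted_positives

    def test_gacc_invariant_to_joint_class_permutation(self, rng):
        g, p = rng.integers(0, 4, (2, 16, 16))
        perm = rng.permutation(4)
        a = global_accuracy(confusion_matrix(g, p))
        b = global_accuracy(confusion_matrix(perm[g], perm[p]))
        assert a == pytest.approx(b, abs=1e-15)
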