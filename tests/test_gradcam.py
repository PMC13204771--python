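"""Grad-CAM attribution and saliency-overlap scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungrg.gradcam import (binarize_top_quantile, dice_from_iou, grad_cam,
                            saliency_scores, score_table, summarize_scores)
from lungrg.model import MultiSliceReportModel, TINY_CONFIG

RNG = np.random.default_rng(0)


class TestGradCam:
    def test_five_nonnegative_maps_per_patient(self, trained_tiny,
                                               tiny_samples):
        s = next(x for x in tiny_samples if x.label == 1)
        maps = grad_cam(trained_tiny, s.pixels, s.label)
        assert len(maps) == 5
        for m in maps:
            assert (m.raw_map >= 0).all()
            assert m.raw_map.shape == (2, 2)  # tiny grid
            assert m.upsampled.shape == (32, 32)

    def test_upsampled_map_min_max_normalized(self, trained_tiny,
                                              tiny_samples):
        found = False
        for s in tiny_samples:
            for m in grad_cam(trained_tiny, s.pixels, s.label):
                assert 0.0 <= m.upsampled.min() and m.upsampled.max() <= 1.0
                if not m.degenerate:
                    assert m.upsampled.min() == 0.0
                    assert m.upsampled.max() == 1.0
                    found = True
        assert found  # the trained model produces informative maps

    def test_zero_gradient_head_yields_all_zero_maps(self, tiny_samples):
        model = MultiSliceReportModel(TINY_CONFIG, np.random.default_rng(4))
        model.head.fc2.weight.data[...] = 0.0  # constant (zero) logits
        model.head.fc2.bias.data[...] = 0.0
        maps = grad_cam(model, tiny_samples[0].pixels, 0)
        for m in maps:
            assert (m.raw_map == 0).all() and m.degenerate

    def test_invalid_class_rejected(self, trained_tiny, tiny_samples):
        with pytest.raises(ValueError):
            grad_cam(trained_tiny, tiny_samples[0].pixels, 5)


class TestBinarization:
    def test_exact_top_fraction_with_ties(self):
        flat = np.zeros(100)
        flat[:20] = 1.0
        mask, degenerate = binarize_top_quantile(flat.reshape(10, 10), 0.2)
        assert not degenerate
        assert mask.sum() == 20
        assert mask.reshape(-1)[:20].all()

    def test_fraction_near_one_covers_almost_everything(self):
        m = RNG.random((10, 10))
        mask, _ = binarize_top_quantile(m, 0.99)
        assert mask.sum() == 99

    def test_constant_map_flagged_empty(self):
        mask, degenerate = binarize_top_quantile(np.full((8, 8), 0.5))
        assert degenerate and mask.sum() == 0

    def test_matches_sorting_oracle_on_random_maps(self):
        for seed in range(5):
            m = np.random.default_rng(seed).random((16, 16))
            mask, _ = binarize_top_quantile(m, 0.2)
            k = int(round(0.2 * m.size))
            thr = np.sort(m.ravel())[::-1][k - 1]  # k-th largest
            assert mask.sum() == k
            assert (mask == (m >= thr)).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            binarize_top_quantile(RNG.random((4, 4)), 1.5)


class TestSaliencyScores:
    def test_identical_mask_and_box(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:6, 3:7] = True
        sal = np.zeros((10, 10))
        sal[4, 4] = 1.0
        s = saliency_scores(m, (2, 3, 6, 7), sal)
        assert s.iou == 1.0 and s.dice == 1.0 and s.pointing_hit

    def test_disjoint_mask_and_box(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0:2, 0:2] = True
        sal = np.zeros((10, 10))
        sal[0, 0] = 1.0
        s = saliency_scores(m, (6, 6, 9, 9), sal)
        assert s.iou == 0.0 and s.dice == 0.0 and not s.pointing_hit

    def test_partial_overlap_pixel_counts(self):
        # 2x2 mask overlapping a 2x2 box on 2 pixels: IoU 1/3, Dice 1/2
        m = np.zeros((6, 6), dtype=bool)
        m[1:3, 1:3] = True
        s = saliency_scores(m, (2, 1, 4, 3), np.zeros((6, 6)))
        assert s.iou == pytest.approx(1 / 3)
        assert s.dice == pytest.approx(1 / 2)

    def test_empty_box_rejected(self):
        with pytest.raises(ValueError):
            saliency_scores(np.zeros((5, 5), dtype=bool), (2, 2, 2, 4),
                            np.zeros((5, 5)))

    def test_pointing_tie_break_first_row_major_maximum(self):
        sal = np.zeros((4, 4))
        sal[1, 1] = sal[3, 3] = 1.0  # tie; first in row-major order wins
        s = saliency_scores(np.ones((4, 4), dtype=bool), (1, 1, 2, 2), sal)
        assert s.pointing_hit

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_dice_iou_identity(self, seed):
        g = np.random.default_rng(seed)
        m = g.random((8, 8)) > 0.5
        box = (int(g.integers(0, 4)), int(g.integers(0, 4)),
               int(g.integers(5, 8)), int(g.integers(5, 8)))
        s = saliency_scores(m, box, g.random((8, 8)))
        assert s.dice == pytest.approx(dice_from_iou(s.iou))


def test_summary_matches_brute_force():
    g = np.random.default_rng(2)
    scores = []
    for i in range(12):
        m = g.random((8, 8)) > 0.6
        s = saliency_scores(m, (1, 1, 6, 6), g.random((8, 8)),
                            label="SCLC" if i % 2 else "NSCLC",
                            patient_id=f"p{i}", slice_index=i % 5)
        scores.append(s)
    table = score_table(scores)
    summary = summarize_scores(scores)
    overall = summary[summary["Class"] == "Overall"].iloc[0]
    assert overall["IoU Mean"] == pytest.approx(table["iou"].mean())
    assert overall["IoU SD"] == pytest.approx(table["iou"].std(ddof=1))
    assert overall["Pointing Game Accuracy"] == pytest.approx(
        table["pointing_hit"].mean())
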