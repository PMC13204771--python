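"""Classification and caption metrics, including in-study worked examples."""

import numpy as np
import pytest

from lungrg.metrics import (as_percent, bleu, caption_metrics, cider,
                            classification_metrics, confidence_analysis,
                            confusion_matrix, meteor, roc_auc, rouge_l,
                            tokenize)
from lungrg.pooling import prediction_from_logits

# confusion matrices fully determined by the published error descriptions
CM_TR = np.array([[26, 0, 0], [1, 23, 1], [0, 0, 26]])
CM_EN = np.array([[26, 0, 0], [1, 22, 2], [0, 1, 25]])


class TestClassificationMetrics:
    def test_turkish_scenario_worked_example(self):
        m = classification_metrics(CM_TR)
        assert as_percent(m["accuracy"]) == 97.40
        assert as_percent(m["macro_f1"]) == 97.35
        assert as_percent(m["macro_specificity"]) == 98.69
        assert as_percent(m["per_class"]["SCLC"]["recall"]) == 92.00
        assert as_percent(m["per_class"]["Normal"]["precision"]) == 96.30

    def test_english_scenario_worked_example(self):
        m = classification_metrics(CM_EN)
        assert as_percent(m["accuracy"]) == 94.81
        assert as_percent(m["macro_specificity"]) == 97.40

    def test_identity_matrix_all_perfect(self):
        m = classification_metrics(np.eye(3, dtype=int) * 10)
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0
        assert m["macro_specificity"] == 1.0

    def test_zero_division_reported_as_nan(self):
        cm = np.array([[5, 0, 0], [3, 0, 0], [2, 0, 0]])
        m = classification_metrics(cm)
        assert np.isnan(m["per_class"]["SCLC"]["precision"])

    def test_micro_accuracy_matches_raw_predictions(self):
        g = np.random.default_rng(0)
        y = g.integers(0, 3, 60)
        p = g.integers(0, 3, 60)
        m = classification_metrics(confusion_matrix(y, p))
        assert m["accuracy"] == pytest.approx((y == p).mean())

    def test_binary_specificity_equals_complement_recall(self):
        cm2 = np.array([[18, 4], [3, 25]])
        m = classification_metrics(cm2, class_names=("A", "B"))
        assert m["per_class"]["A"]["specificity"] == \
            pytest.approx(m["per_class"]["B"]["recall"])


class TestRocAuc:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1, 2, 2]
        p = np.eye(3)[y] * 0.8 + 0.1 / 1.5  # peaked on the true class
        p = p / p.sum(axis=1, keepdims=True)
        auc = roc_auc(y, p)
        assert all(v == 1.0 for v in auc.values())

    def test_random_scores_near_half(self):
        g = np.random.default_rng(1)
        y = g.integers(0, 3, 2000)
        p = g.dirichlet(np.ones(3), 2000)
        auc = roc_auc(y, p)
        for v in auc.values():
            assert abs(v - 0.5) < 0.05

    def test_invariant_under_monotone_transform_of_scores(self):
        g = np.random.default_rng(2)
        y = g.integers(0, 2, 100)
        from sklearn.metrics import roc_auc_score
        s = g.random(100)
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(3 * s)))

    def test_single_class_truth_flagged(self):
        p = np.full((4, 3), 1 / 3)
        auc = roc_auc([1, 1, 1, 1], p)
        assert np.isnan(auc["Normal"])


class TestBleu:
    def test_identity_scores_one(self):
        scores = bleu(["a b c d e"], ["a b c d e"])
        assert scores == pytest.approx([1.0] * 4)

    def test_no_shared_tokens_scores_zero(self):
        assert bleu(["a b"], ["c d"])[0] == 0.0

    def test_two_of_three_unigrams(self):
        assert bleu(["a b c"], ["a b d"])[0] == pytest.approx(2 / 3)

    def test_nonincreasing_in_n(self):
        cands = ["the solid mass lesion is observed in the right lung"]
        refs = ["a solid mass is observed in the left lung today"]
        scores = bleu(cands, refs)
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_brevity_penalty_punishes_short_candidates(self):
        full = bleu(["a b c d"], ["a b c d"])[0]
        short = bleu(["a b"], ["a b c d"])[0]
        assert short < full


class TestOtherCaptionMetrics:
    def test_rouge_identity(self):
        assert rouge_l(["x y z"], ["x y z"]) == 1.0

    def test_rouge_lcs_fraction(self):
        # LCS("a b c", "a c") = 2; P = 2/3, R = 1 -> F1 = 0.8
        assert rouge_l(["a b c"], ["a c"]) == pytest.approx(0.8)

    def test_meteor_identity_close_to_one(self):
        # exact alignment, single chunk: F * (1 - 0.5/(m^3)) < 1 by design
        v = meteor(["a b c"], ["a b c"])
        assert v == pytest.approx(1.0 - 0.5 * (1 / 3) ** 3)

    def test_meteor_zero_without_matches(self):
        assert meteor(["a b"], ["c d"]) == 0.0

    def test_cider_identity_positive_and_bounded(self):
        v = cider(["a b c d", "e f g h"], ["a b c d", "e f g h"])
        assert 0.0 < v <= 10.0

    def test_empty_candidate_warns_and_scores_zero(self):
        with pytest.warns(UserWarning):
            scores = caption_metrics([""], ["a b"])
        assert scores.bleu[0] == 0.0 and scores.rouge_l == 0.0

    def test_tokenizer_is_case_and_punctuation_insensitive(self):
        assert tokenize("A 24 mm Mass, observed.") == \
            ["a", "24", "mm", "mass", "observed"]


class TestConfidenceAnalysis:
    def test_one_hot_correct_predictions(self):
        preds = [prediction_from_logits(np.array([100.0, 0, 0])),
                 prediction_from_logits(np.array([0, 100.0, 0]))]
        out = confidence_analysis(preds, [0, 1])
        assert out["correct"]["n"] == 2
        assert out["correct"]["mean"] == pytest.approx(1.0)
        assert out["incorrect"]["n"] == 0

    def test_uniform_predictions_have_third_confidence(self):
        preds = [prediction_from_logits(np.zeros(3)) for _ in range(3)]
        out = confidence_analysis(preds, [0, 1, 2])
        for r in out["records"]:
            assert r["max_confidence"] == pytest.approx(1 / 3)

    def test_group_means_match_brute_force(self):
        g = np.random.default_rng(3)
        preds = [prediction_from_logits(g.normal(size=3)) for _ in range(40)]
        truths = g.integers(0, 3, 40)
        out = confidence_analysis(preds, truths)
        manual = [p.max_confidence for p, t in zip(preds, truths)
                  if p.predicted_class == t]
        assert out["correct"]["mean"] == pytest.approx(np.mean(manual))
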