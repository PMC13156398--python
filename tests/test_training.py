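"""Losses, class weighting, the split protocol, the metric panel, and
training-loop semantics."""

import numpy as np
import pytest

from evidfuse.autodiff import Tensor
from evidfuse.encoders import StructuredEncoderConfig, TextEncoderConfig
from evidfuse.evidence import EMConfig
from evidfuse.fusion import FusionSpec
from evidfuse.synthetic import CohortSpec, generate
from evidfuse.training import (EvalReport, TrainConfig, aux_loss,
                               class_weights, compute_metrics, main_loss,
                               overall_loss, run_experiment,
                               stratified_splits)

LN2 = np.log(2.0)


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        np.testing.assert_allclose(class_weights(np.array([0, 1] * 10)), [1.0, 1.0])

    def test_imbalanced_hand_case(self):
        # N=100, N_pos=10: w_pos = 100/(2*10) = 5, w_neg = 100/(2*90)
        labels = np.array([1] * 10 + [0] * 90)
        w = class_weights(labels)
        assert w[1] == pytest.approx(5.0)
        assert w[0] == pytest.approx(100 / 180)

    def test_invariant_to_label_order(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 10 + [0] * 90)
        np.testing.assert_allclose(class_weights(labels),
                                   class_weights(rng.permutation(labels)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(10, dtype=int))


class TestLosses:
    def test_perfect_predictions_give_zero_main_loss(self):
        p = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert float(main_loss(p, y, np.ones(2)).data) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_ln2(self):
        p = Tensor(np.full((8, 2), 0.5))
        y = np.eye(2)[np.array([0, 1] * 4)]
        assert float(main_loss(p, y, np.ones(2)).data) == pytest.approx(LN2, abs=1e-12)

    def test_weighted_hand_case(self):
        # -(1/2) * (2*ln 0.8 + 1*ln 0.7) evaluated by hand
        p = Tensor(np.array([[0.8, 0.2], [0.3, 0.7]]))
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = float(main_loss(p, y, np.array([2.0, 1.0])).data)
        expect = -0.5 * (2.0 * np.log(0.8) + np.log(0.7))  # = 0.4014810233
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.40148, abs=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            main_loss(Tensor(np.ones((2, 2))), np.ones((3, 2)), np.ones(2))

    def test_aux_confident_correct_is_near_zero(self):
        logits = Tensor(np.array([[30.0, -30.0]]))
        y = np.array([[1.0, 0.0]])
        assert float(aux_loss(logits, y, np.ones(2)).data) == pytest.approx(0.0, abs=1e-12)

    def test_aux_zero_logits_is_ln2(self):
        logits = Tensor(np.zeros((4, 2)))
        y = np.eye(2)[np.array([0, 1, 0, 1])]
        assert float(aux_loss(logits, y, np.ones(2)).data) == pytest.approx(LN2, abs=1e-12)

    def test_aux_hand_softmax_case(self):
        # softmax(1, -1) = (e^2/(1+e^2), 1/(1+e^2)); true class 0, w = (3, 1)
        logits = Tensor(np.array([[1.0, -1.0]]))
        y = np.array([[1.0, 0.0]])
        expect = -3.0 * np.log(np.exp(2.0) / (1.0 + np.exp(2.0)))
        got = float(aux_loss(logits, y, np.array([3.0, 1.0])).data)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_overall_loss_defaults_and_linearity(self):
        cfg = TrainConfig()  # alpha=2, beta=1
        assert overall_loss(0.5, 0.2, 0.3, cfg) == pytest.approx(1.2)
        cfg0 = TrainConfig(alpha=0.0, beta=0.0)
        assert overall_loss(0.7, 9.0, 9.0, cfg0) == pytest.approx(0.7)
        # linearity in each component
        assert overall_loss(1.0, 0.0, 0.0, cfg) + overall_loss(0.0, 1.0, 0.0, cfg) \
            == pytest.approx(overall_loss(1.0, 1.0, 0.0, cfg))

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(alpha=-1.0)


class TestSplits:
    def test_holdout_partitions_and_fractions(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(1000) < 0.12).astype(int)
        cfg = TrainConfig()
        holdout, folds = stratified_splits(labels, cfg, seed=3)
        all_idx = np.concatenate([holdout.train, holdout.val, holdout.test])
        assert sorted(all_idx.tolist()) == list(range(1000))
        assert len(holdout.train) == 600 and len(holdout.val) == 200

    def test_fold_prevalence_within_one_count(self):
        rng = np.random.default_rng(1)
        labels = (rng.random(500) < 0.12).astype(int)
        cfg = TrainConfig()
        _, folds = stratified_splits(labels, cfg, seed=3)
        global_pos = labels.sum()
        tests = []
        for sp in folds:
            tests.extend(sp.test.tolist())
            expected = global_pos * len(sp.test) / len(labels)
            assert abs(labels[sp.test].sum() - expected) <= 1.0
        assert sorted(tests) == list(range(500))

    def test_same_seed_same_folds(self):
        labels = np.array([0, 1] * 100)
        cfg = TrainConfig()
        a, fa = stratified_splits(labels, cfg, seed=5)
        b, fb = stratified_splits(labels, cfg, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        for x, y in zip(fa, fb):
            np.testing.assert_array_equal(x.test, y.test)


class TestMetrics:
    @staticmethod
    def _from_confusion(tp, fp, fn, tn):
        p = np.concatenate([
            np.full(tp, 0.9), np.full(fn, 0.1),
            np.full(fp, 0.9), np.full(tn, 0.1),
        ])
        o = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)])
        return p, o

    def test_hand_derived_confusion_fixture(self):
        p, o = self._from_confusion(tp=30, fp=10, fn=20, tn=40)
        m = compute_metrics(p, o)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.60)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["npv"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["bacc"] == pytest.approx(0.70)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_scores(self):
        p = np.array([1.0, 0.0, 1.0, 0.0])
        o = np.array([1, 0, 1, 0])
        m = compute_metrics(p, o)
        assert m["brier"] == pytest.approx(0.0)
        assert m["nll"] == pytest.approx(0.0, abs=1e-10)

    def test_brier_hand_fixture(self):
        # (0.8 with o=1, 0.3 with o=0): ((0.2)^2 + (0.3)^2)/2 = 0.065
        m = compute_metrics(np.array([0.8, 0.3]), np.array([1, 0]))
        assert m["brier"] == pytest.approx(0.065)

    def test_bacc_identity_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            p, o = self._from_confusion(tp, fp, fn, tn)
            m = compute_metrics(p, o)
            assert m["bacc"] == pytest.approx((m["recall"] + m["specificity"]) / 2)

    def test_degenerate_cells_are_missing_not_zero(self):
        # nothing predicted positive -> precision undefined
        m = compute_metrics(np.array([0.1, 0.2, 0.3]), np.array([0, 1, 0]))
        assert np.isnan(m["precision"])
        assert not np.isnan(m["recall"])

    def test_random_scorer_auroc_near_half(self):
        rng = np.random.default_rng(12)
        n = 2000
        labels = np.array([0, 1] * (n // 2))
        p = rng.random(n)
        m = compute_metrics(p, labels)
        assert abs(m["auroc"] - 0.5) < 0.05

    def test_report_mean_and_stderr_skip_missing(self):
        rep = EvalReport()
        rep.add({"precision": 0.5, "recall": 0.6})
        rep.add({"precision": float("nan"), "recall": 0.8})
        s = rep.summary()
        assert s["precision"]["mean"] == pytest.approx(0.5)
        assert s["precision"]["n_folds"] == 1
        assert s["recall"]["mean"] == pytest.approx(0.7)
        assert s["recall"]["se"] == pytest.approx(np.std([0.6, 0.8], ddof=1) / np.sqrt(2))


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate(CohortSpec(n_patients=260, seed=4))


class TestTrainingLoop:
    CFG = dict(max_epochs=3, patience=3, seed=9)

    def _run(self, raw, **overrides):
        cfg = TrainConfig(**{**self.CFG, **overrides})
        return run_experiment(
            raw, StructuredEncoderConfig(), TextEncoderConfig(),
            EMConfig(n_prototypes=5), FusionSpec(), cfg, mode="holdout",
        )

    def test_same_seed_identical_history(self, tiny_cohort):
        a = self._run(tiny_cohort)
        b = self._run(tiny_cohort)
        assert a.histories == b.histories
        np.testing.assert_array_equal(
            a.predictions[0]["p_positive"].to_numpy(),
            b.predictions[0]["p_positive"].to_numpy(),
        )

    def test_training_reduces_loss_on_separable_data(self):
        from evidfuse.synthetic import separable_spec
        raw = generate(CohortSpec(**{**separable_spec(7).__dict__,
                                     "n_patients": 400}))
        res = self._run(raw, max_epochs=6)
        hist = res.histories[0]
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_early_stopping_respects_patience(self, tiny_cohort):
        res = self._run(tiny_cohort, max_epochs=12, patience=0)
        hist = res.histories[0]
        # with patience 0 the loop stops right after the first epoch whose
        # validation loss fails to improve on the best so far
        val = [h["val_loss"] for h in hist]
        best = np.inf
        for i, v in enumerate(val[:-1]):
            assert v < best  # every non-final epoch improved
            best = v
        assert len(hist) <= 12

    def test_cv_mode_produces_fold_rows(self, tiny_cohort):
        cfg = TrainConfig(max_epochs=2, patience=1, seed=1, n_folds=3)
        res = run_experiment(
            tiny_cohort, StructuredEncoderConfig(), TextEncoderConfig(),
            EMConfig(n_prototypes=4), FusionSpec(), cfg, mode="cv",
        )
        assert len(res.report.rows) == 3
        frame = res.report.to_frame()
        assert list(frame.index[-2:]) == ["mean", "se"]
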