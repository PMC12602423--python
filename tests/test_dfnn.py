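"""Network construction, training behavior, and the metric suite."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paddycd as p
from paddycd import dfnn
from paddycd.scene import BAND_COLUMNS


def two_class_table(n, rng, separation=4.0):
    """Linearly separable standardized 2-class blobs."""
    half = n // 2
    x0 = rng.normal(-separation / 2, 1.0, size=(half, 5))
    x1 = rng.normal(separation / 2, 1.0, size=(n - half, 5))
    t = pd.DataFrame(np.vstack([x0, x1]), columns=list(BAND_COLUMNS))
    t["label"] = np.r_[np.zeros(half, int), np.ones(n - half, int)]
    t["date"] = "34DAS"
    t["treatment"] = "T0"
    return t.sample(frac=1.0, random_state=0).reset_index(drop=True)


class TestBuildModel:
    @pytest.mark.parametrize("n_classes,expected", [(3, 483), (2, 467)])
    def test_parameter_count(self, n_classes, expected):
        assert p.ModelSpec(n_classes=n_classes).parameter_count() == expected

    def test_same_seed_identical_weights(self):
        a = p.build_model(p.ModelSpec(), seed=7)
        b = p.build_model(p.ModelSpec(), seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_weight_shapes(self):
        m = p.build_model(p.ModelSpec(n_classes=3), seed=0)
        shapes = [w.shape for w in m.weights]
        assert shapes == [(5, 20), (20,), (20, 15), (15,), (15, 3), (3,)]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            p.ModelSpec(dropout=1.0)
        with pytest.raises(ValueError):
            p.ModelSpec(n_classes=1)


class TestTrain:
    def test_separable_two_class_reaches_high_accuracy(self, rng):
        t = two_class_table(2000, rng)
        tr, va, te = p.shuffle_split(t, p.SplitSpec(seed=1))
        model = p.build_model(p.ModelSpec(n_classes=2), seed=2)
        # data already standardized by construction; identity scaler
        scaler = p.ScalerParams(mean=np.zeros(5), sd=np.ones(5))
        fitted = p.train(model, tr, va, p.TrainingConfig(seed=3), scaler=scaler)
        acc = (fitted.history.val_accuracy.iloc[-1])
        report = p.evaluate(fitted, te)
        assert acc >= 0.99
        assert report.accuracy >= 99.0

    def test_patience_zero_one_epoch_history(self, rng):
        t = two_class_table(200, rng)
        tr, va, _ = p.shuffle_split(t, p.SplitSpec(seed=1))
        model = p.build_model(p.ModelSpec(n_classes=2), seed=2)
        cfg = p.TrainingConfig(max_epochs=1, patience=0, seed=3)
        fitted = p.train(model, tr, va, cfg,
                         scaler=p.ScalerParams(np.zeros(5), np.ones(5)))
        assert len(fitted.history) == 1

    def test_label_outside_ordering_rejected(self, rng):
        t = two_class_table(100, rng)
        t.loc[0, "label"] = 7
        tr, va, _ = p.shuffle_split(t, p.SplitSpec(seed=1))
        model = p.build_model(p.ModelSpec(n_classes=2), seed=2)
        with pytest.raises(ValueError, match="7"):
            p.train(model, t, t, p.TrainingConfig(seed=0))

    def test_unstandardized_input_warns(self, rng):
        t = two_class_table(1200, rng)
        t[list(BAND_COLUMNS)] += 5.0  # raw-reflectance-scale offset
        model = p.build_model(p.ModelSpec(n_classes=2), seed=2)
        cfg = p.TrainingConfig(max_epochs=1, seed=0)
        with pytest.warns(UserWarning, match="standardized"):
            p.train(model, t, t, cfg,
                    scaler=p.ScalerParams(np.zeros(5), np.ones(5)))


class TestPredict:
    def test_probabilities_sum_to_one(self, t1_model, rng):
        x = rng.random((64, 5))
        probs = p.predict_proba(t1_model, x)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic_despite_dropout(self, t1_model, rng):
        x = np.repeat(rng.random((1, 5)), 50, axis=0)
        probs = p.predict_proba(t1_model, x)
        assert (probs == probs[0]).all()

    def test_class_mean_spectra_classified_correctly(self, t1_model):
        sigs = p.default_signatures()
        means = np.stack([sigs[c].mean for c in (0, 1, 2)])
        labels = p.predict_label(t1_model, means)
        np.testing.assert_array_equal(labels, [0, 1, 2])

    def test_wrong_band_count_rejected(self, t1_model):
        with pytest.raises(ValueError, match="bands"):
            p.predict_proba(t1_model, np.zeros((3, 4)))

    def test_untrained_or_scalerless_model_rejected(self):
        m = p.build_model(p.ModelSpec(), seed=0)
        with pytest.raises(ValueError, match="not trained"):
            p.predict_proba(m, np.zeros((1, 5)))

    def test_serialization_roundtrip_bit_identical(self, t1_model, tmp_path, rng):
        t1_model.save(tmp_path / "bundle")
        back = p.FittedModel.load(tmp_path / "bundle")
        x = rng.random((100, 5))
        np.testing.assert_array_equal(
            p.predict_proba(t1_model, x), p.predict_proba(back, x))


class TestMetrics:
    @pytest.mark.parametrize("cm,expected", [
        ([[50, 0], [0, 50]], 100.0),
        ([[40, 10], [10, 40]], 80.0),
        ([[25, 25], [25, 25]], 50.0),
    ])
    def test_overall_accuracy(self, cm, expected):
        assert p.dfnn.overall_accuracy(np.array(cm)) == pytest.approx(expected)

    @pytest.mark.parametrize("cm,expected", [
        ([[50, 0], [0, 50]], 1.0),
        ([[25, 25], [25, 25]], 0.0),
        ([[40, 10], [10, 40]], 0.6),
    ])
    def test_kappa(self, cm, expected):
        assert dfnn.kappa(np.array(cm)) == pytest.approx(expected, abs=1e-12)

    def test_kappa_undefined_at_full_chance_agreement(self):
        with pytest.raises(ValueError):
            dfnn.kappa(np.array([[5, 0], [0, 0]]))

    def test_cross_entropy_closed_forms(self):
        onehot = np.eye(3)
        assert dfnn.cross_entropy(onehot, onehot) == pytest.approx(0.0, abs=1e-10)
        uniform = np.full((3, 3), 1 / 3)
        assert dfnn.cross_entropy(onehot, uniform) == pytest.approx(math.log(3))
        y = np.array([[1.0, 0.0]])
        prob = np.array([[0.5, 0.5]])
        assert dfnn.cross_entropy(y, prob) == pytest.approx(math.log(2))

    def test_mse_closed_forms(self):
        onehot = np.eye(3)
        assert dfnn.mean_squared_error(onehot, onehot) == 0.0
        uniform = np.full((3, 3), 1 / 3)
        assert dfnn.mean_squared_error(onehot, uniform) == pytest.approx(2 / 9)
        y = np.array([[1.0, 0.0]])
        flipped = np.array([[0.0, 1.0]])
        assert dfnn.mean_squared_error(y, flipped) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dfnn.cross_entropy(np.eye(3), np.eye(2))

    def test_per_class_prf_counts(self):
        cm = np.array([[40, 10], [10, 40]])
        prf = dfnn.per_class_prf(cm)
        np.testing.assert_allclose(
            prf.loc[0, ["precision", "recall", "f1"]].to_numpy(dtype=float),
            [0.8, 0.8, 0.8], atol=1e-12)

    def test_perfect_diagonal_gives_unit_prf(self):
        prf = dfnn.per_class_prf(np.diag([5, 7, 9]))
        assert (prf[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_never_predicted_class_flagged(self):
        cm = np.array([[10, 0], [5, 0]])  # class 1 never predicted
        prf = dfnn.per_class_prf(cm)
        assert prf.loc[1, "precision"] == 0.0
        assert "precision" in prf.loc[1, "degenerate"]

    def test_metrics_match_sklearn_on_random_predictions(self, rng):
        """Independent oracle: sklearn computes the same confusion-matrix
        statistics from the same label pairs."""
        from sklearn import metrics as skm

        ref = rng.integers(0, 3, 500)
        pred = np.where(rng.random(500) < 0.8, ref, rng.integers(0, 3, 500))
        cm = dfnn.confusion_matrix(ref, pred, (0, 1, 2))
        np.testing.assert_array_equal(cm, skm.confusion_matrix(ref, pred))
        assert dfnn.overall_accuracy(cm) == pytest.approx(
            100 * skm.accuracy_score(ref, pred))
        assert dfnn.kappa(cm) == pytest.approx(skm.cohen_kappa_score(ref, pred))
        prf = dfnn.per_class_prf(cm)
        sk_p, sk_r, sk_f, _ = skm.precision_recall_fscore_support(ref, pred)
        np.testing.assert_allclose(prf.precision, sk_p, atol=1e-12)
        np.testing.assert_allclose(prf.recall, sk_r, atol=1e-12)
        np.testing.assert_allclose(prf.f1, sk_f, atol=1e-12)

    def test_cross_entropy_matches_sklearn_log_loss(self, rng):
        from sklearn.metrics import log_loss

        y = rng.integers(0, 3, 200)
        probs = rng.dirichlet(np.ones(3), size=200)
        onehot = np.eye(3)[y]
        assert dfnn.cross_entropy(onehot, probs) == pytest.approx(
            log_loss(y, probs, labels=[0, 1, 2]), rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_kappa_never_exceeds_accuracy(self, seed):
        """kappa <= OA/100 for every nonnegative matrix (chance-corrected
        agreement cannot beat raw agreement)."""
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 5))
        cm = r.integers(0, 50, size=(k, k))
        if cm.sum() == 0:
            cm[0, 0] = 1
        try:
            assert dfnn.kappa(cm) <= dfnn.overall_accuracy(cm) / 100 + 1e-12
        except ValueError:
            pass  # p_e == 1 is legitimately undefined

    def test_micro_recall_equals_overall_accuracy(self, rng):
        cm = rng.integers(0, 50, size=(3, 3))
        prf = dfnn.per_class_prf(cm)
        weights = cm.sum(axis=1) / cm.sum()
        micro = (prf.recall * weights).sum()
        assert micro == pytest.approx(dfnn.overall_accuracy(cm) / 100)


class TestEvaluate:
    def test_synthetic_regime_reaches_paper_analog_accuracy(
            self, t1_model, t1_test_table):
        report = p.evaluate(t1_model, t1_test_table)
        assert report.accuracy >= 97.0
        assert report.kappa >= 0.95

    def test_report_internally_consistent(self, t1_model, t1_test_table):
        report = p.evaluate(t1_model, t1_test_table)
        assert report.accuracy == dfnn.overall_accuracy(report.confusion)
        assert report.kappa == pytest.approx(dfnn.kappa(report.confusion),
                                             abs=1e-12)
        assert report.kappa <= report.accuracy / 100
        pd.testing.assert_frame_equal(report.per_class,
                                      dfnn.per_class_prf(report.confusion))

    def test_empty_table_rejected(self, t1_model, t1_test_table):
        with pytest.raises(ValueError, match="empty"):
            p.evaluate(t1_model, t1_test_table.iloc[:0])
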