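import numpy as np
import pytest

from blastograde import grading
from blastograde.grading import Architecture


class TestSplitDataset:
    def test_canonical_proportions(self, feature_dataset):
        x, y = feature_dataset
        (xtr, ytr), (xva, yva), (xte, yte) = grading.split_dataset(x, y, seed=0)
        n = len(y)
        assert len(ytr) == pytest.approx(0.70 * n, abs=3)
        assert len(yva) == pytest.approx(0.15 * n, abs=3)
        assert len(yte) == pytest.approx(0.15 * n, abs=3)
        assert len(ytr) + len(yva) + len(yte) == n

    def test_deterministic(self, feature_dataset):
        x, y = feature_dataset
        a = grading.split_dataset(x, y, seed=9)
        b = grading.split_dataset(x, y, seed=9)
        for (xa, ya), (xb, yb) in zip(a, b):
            np.testing.assert_array_equal(xa, xb)
            np.testing.assert_array_equal(ya, yb)

    def test_small_balanced_set_keeps_all_classes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(21, 4))
        y = np.repeat([1, 2, 3], 7)
        for part in grading.split_dataset(x, y, seed=1):
            assert set(part[1]) == {1, 2, 3}

    def test_missing_class_rejected(self):
        x = np.zeros((30, 4))
        y = np.repeat([1, 2], 15)
        with pytest.raises(grading.StratificationError):
            grading.split_dataset(x, y, seed=0)


class TestTrainAnn:
    @pytest.mark.parametrize("train_fn", ["rprop", "gradient_descent_momentum"])
    def test_separable_data_high_accuracy(self, feature_dataset, train_fn):
        x, y = feature_dataset
        split = grading.split_dataset(x, y, seed=0)
        ann = grading.train_ann(split[0], split[1],
                                Architecture(train_fn=train_fn), seed=0)
        assert grading.accuracy(ann, split[2][0], split[2][1]) >= 0.95

    def test_zero_epoch_budget_returns_initialized_net(self, feature_dataset):
        x, y = feature_dataset
        split = grading.split_dataset(x, y, seed=0)
        ann = grading.train_ann(split[0], split[1], Architecture(), seed=0,
                                max_epochs=0)
        assert ann.training_log == []
        assert len(ann.weights) == 2  # one hidden layer + output

    def test_deterministic_weights(self, feature_dataset):
        x, y = feature_dataset
        split = grading.split_dataset(x, y, seed=0)
        a = grading.train_ann(split[0], split[1], Architecture(), seed=3)
        b = grading.train_ann(split[0], split[1], Architecture(), seed=3)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_plain_gd_loss_non_increasing_single_layer(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 4))
        y = (np.arange(60) % 3) + 1
        arch = Architecture(n_hidden1=1, tf_hidden1="linear", tf_output="linear",
                            train_fn="gradient_descent", n_hidden_layers=1)
        ann = grading.train_ann((x, y), (x, y), arch, seed=0, max_epochs=80,
                                patience=80, learning_rate=0.01)
        losses = [e["train_loss"] for e in ann.training_log]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_save_load_roundtrip(self, feature_dataset, tmp_path):
        x, y = feature_dataset
        split = grading.split_dataset(x, y, seed=0)
        ann = grading.train_ann(split[0], split[1], Architecture(), seed=0)
        p = tmp_path / "model.json"
        ann.save(p)
        loaded = grading.TrainedANN.load(p)
        np.testing.assert_allclose(ann.scores(x[:5]), loaded.scores(x[:5]))


class TestPredict:
    def _identity_net(self):
        arch = Architecture(n_hidden1=3, tf_hidden1="linear", tf_output="linear")
        return grading.TrainedANN(
            architecture=arch,
            weights=[np.eye(3), np.eye(3)],
            biases=[np.zeros(3), np.zeros(3)],
            input_schema=("a", "b", "c"),
            norm_mean=np.zeros(3), norm_std=np.ones(3))

    def test_forward_pass_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        arch = Architecture(n_hidden1=4, tf_hidden1="tanh_sigmoid",
                            tf_output="logistic_sigmoid")
        w1 = rng.normal(size=(5, 4))
        b1 = rng.normal(size=4)
        w2 = rng.normal(size=(4, 3))
        b2 = rng.normal(size=3)
        ann = grading.TrainedANN(architecture=arch, weights=[w1, w2],
                                 biases=[b1, b2],
                                 input_schema=tuple("abcde"),
                                 norm_mean=np.zeros(5), norm_std=np.ones(5))
        x = rng.normal(size=5)
        hidden = np.array([np.tanh(sum(x[i] * w1[i, j] for i in range(5)) + b1[j])
                           for j in range(4)])
        raw = np.array([1 / (1 + np.exp(-(sum(hidden[j] * w2[j, k] for j in range(4))
                                          + b2[k]))) for k in range(3)])
        expected = np.exp(raw) / np.exp(raw).sum()
        np.testing.assert_allclose(ann.scores(x)[0], expected, atol=1e-9)

    def test_argmax_grade(self):
        ann = self._identity_net()
        grade, scores = grading.predict(ann, np.array([0.2, 0.2, 0.6]))
        assert grade == 3

    def test_tie_breaks_to_worse_grade(self):
        ann = self._identity_net()
        grade, _ = grading.predict(ann, np.array([0.4, 0.4, 0.2]))
        assert grade == 2

    def test_schema_mismatch_rejected(self):
        with pytest.raises(grading.SchemaError):
            grading.predict(self._identity_net(), np.zeros(5))


class TestEnsemble:
    def _const_net(self, grade):
        arch = Architecture(n_hidden1=1, tf_hidden1="linear", tf_output="linear")
        w2 = np.zeros((1, 3))
        b2 = np.zeros(3)
        b2[grade - 1] = 5.0
        return grading.TrainedANN(architecture=arch,
                                  weights=[np.zeros((2, 1)), w2],
                                  biases=[np.zeros(1), b2],
                                  input_schema=("a", "b"),
                                  norm_mean=np.zeros(2), norm_std=np.ones(2))

    def test_majority_mode(self):
        anns = [self._const_net(1), self._const_net(2), self._const_net(1)]
        pred = grading.ensemble_predict(anns, np.zeros(2))
        assert pred.mode_grade == 1 and pred.final_grade == 1

    def test_unanimity(self):
        anns = [self._const_net(2)] * 3
        pred = grading.ensemble_predict(anns, np.zeros(2))
        assert pred.mode_grade == 2

    def test_three_way_disagreement_median_fallback(self):
        anns = [self._const_net(1), self._const_net(2), self._const_net(3)]
        pred = grading.ensemble_predict(anns, np.zeros(2))
        assert pred.mode_grade is None
        assert pred.final_grade == 2

    def test_permutation_invariant(self):
        import itertools
        nets = [self._const_net(1), self._const_net(3), self._const_net(1)]
        outs = {grading.ensemble_predict(list(p), np.zeros(2)).final_grade
                for p in itertools.permutations(nets)}
        assert outs == {1}

    def test_wrong_ensemble_size_rejected(self):
        with pytest.raises(grading.EnsembleSizeError):
            grading.ensemble_predict([self._const_net(1)] * 2, np.zeros(2))
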