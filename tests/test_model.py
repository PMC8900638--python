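import numpy as np
import pytest

import dynergy as dg
from dynergy.model import (
    NetworkSpec,
    baseline_svm,
    build_network,
    evaluate_kfold,
    evaluate_loso,
    svm_penalty_grid,
    train,
)
from dynergy.signal_io import ValidationError

from .conftest import small_netspec


class TestNetworkSpec:
    def test_defaults_match_published_architecture(self):
        spec = NetworkSpec()
        assert (spec.bilstm_units, spec.dropout, spec.lstm_units,
                spec.dense1) == (128, 0.3, 64, 128)
        assert spec.optimizer == "rmsprop"
        assert spec.learning_rate == 0.001

    @pytest.mark.parametrize("bad", [
        dict(input_size=0), dict(dropout=1.0), dict(n_classes=1),
        dict(optimizer="adam"), dict(epochs=-1),
    ])
    def test_invalid_specs(self, bad):
        with pytest.raises(ValidationError):
            NetworkSpec(**bad)


class TestBuildNetwork:
    def test_output_width_three_classes(self, rng):
        spec = small_netspec(input_size=17, n_classes=3)
        net = build_network(spec)
        logits = net.forward(rng.standard_normal((2, 5, 17)))
        assert logits.shape == (2, 3)

    def test_output_width_two_classes(self, rng):
        spec = small_netspec(input_size=19, n_classes=2)
        net = build_network(spec)
        assert net.forward(rng.standard_normal((1, 5, 19))).shape == (1, 2)

    def test_same_seed_identical_parameters(self):
        spec = small_netspec(seed=9)
        a, b = build_network(spec), build_network(spec)
        for k, v in a.params.items():
            np.testing.assert_array_equal(v, b.params[k])


class TestTrain:
    def test_zero_epochs_leaves_parameters(self, cheap_sequences, cheap_bundle):
        spec = small_netspec(epochs=0)
        net = build_network(spec)
        before = {k: v.copy() for k, v in net.params.items()}
        train(net, cheap_sequences[:40], cheap_bundle.labels[:40], spec)
        for k, v in net.params.items():
            np.testing.assert_array_equal(v, before[k])

    def test_single_class_rejected(self, cheap_sequences):
        spec = small_netspec()
        with pytest.raises(ValidationError):
            train(build_network(spec), cheap_sequences[:10],
                  np.zeros(10, dtype=int), spec)

    def test_separable_data_high_train_accuracy(self, cheap_sequences,
                                                cheap_bundle):
        # 200 separable trials; loss must fall and train accuracy clear 0.95
        spec = small_netspec(epochs=10, seed=7)
        net = build_network(spec)
        trained = train(net, cheap_sequences, cheap_bundle.labels, spec)
        assert trained.loss_history[-1] < trained.loss_history[0]
        acc = (trained.predict(cheap_sequences) == cheap_bundle.labels).mean()
        assert acc >= 0.95

    def test_shuffled_labels_at_chance(self, cheap_sequences, cheap_bundle):
        rng = np.random.default_rng(13)
        y = rng.permutation(cheap_bundle.labels)
        split = 160
        spec = small_netspec(epochs=10, seed=13)
        trained = train(build_network(spec), cheap_sequences[:split],
                        y[:split], spec)
        acc = (trained.predict(cheap_sequences[split:]) == y[split:]).mean()
        assert abs(acc - 0.5) <= 0.25  # small held-out set: generous but bounded


class TestLOSO:
    def test_one_fold_per_subject(self, cheap_bundle, cheap_sequences):
        spec = small_netspec(epochs=2)
        sub = np.flatnonzero(cheap_bundle.subjects < 3)
        bundle = dg.DatasetBundle(
            [cheap_bundle.recordings[i] for i in sub],
            cheap_bundle.labels[sub], cheap_bundle.subjects[sub])
        report = evaluate_loso(bundle, spec, sequences=cheap_sequences[sub])
        assert report.protocol == "loso"
        assert sorted(report.unit_ids) == [0, 1, 2]
        assert report.mean_accuracy == pytest.approx(
            np.mean(report.accuracies))

    def test_recoverable_signal_above_080(self, cheap_bundle,
                                          cheap_sequences):
        spec = small_netspec(epochs=10, seed=11)
        report = evaluate_loso(cheap_bundle, spec,
                               sequences=cheap_sequences)
        assert report.mean_accuracy > 0.8

    def test_needs_two_subjects(self, cheap_bundle, cheap_sequences):
        sub = np.flatnonzero(cheap_bundle.subjects == 0)
        bundle = dg.DatasetBundle(
            [cheap_bundle.recordings[i] for i in sub],
            cheap_bundle.labels[sub], cheap_bundle.subjects[sub])
        with pytest.raises(ValidationError):
            evaluate_loso(bundle, small_netspec(), sequences=cheap_sequences[sub])


class TestKFold:
    def test_fold_geometry(self, cheap_bundle, cheap_sequences):
        from sklearn.model_selection import StratifiedKFold

        y = cheap_bundle.labels[:100]
        splitter = StratifiedKFold(10, shuffle=True, random_state=0)
        test_sets = [set(te) for _, te in
                     splitter.split(np.zeros((100, 1)), y)]
        assert all(len(s) == 10 for s in test_sets)
        union = set().union(*test_sets)
        assert union == set(range(100))
        for i, a in enumerate(test_sets):
            for b in test_sets[i + 1:]:
                assert not (a & b)

    def test_report_and_determinism(self, cheap_bundle, cheap_sequences):
        spec = small_netspec(epochs=3)
        kwargs = dict(k=5, seed=4, sequences=cheap_sequences[:60])
        sub = np.arange(60)
        bundle = dg.DatasetBundle(
            [cheap_bundle.recordings[i] for i in sub],
            cheap_bundle.labels[sub], cheap_bundle.subjects[sub])
        a = evaluate_kfold(bundle, spec, **kwargs)
        b = evaluate_kfold(bundle, spec, **kwargs)
        assert a.accuracies == b.accuracies
        assert a.protocol == "kfold5"

    def test_k_exceeding_trials(self, cheap_bundle, cheap_sequences):
        sub = np.arange(5)
        bundle = dg.DatasetBundle(
            [cheap_bundle.recordings[i] for i in sub],
            cheap_bundle.labels[sub], cheap_bundle.subjects[sub])
        with pytest.raises(ValidationError):
            evaluate_kfold(bundle, small_netspec(), k=10,
                           sequences=cheap_sequences[sub])


class TestBaselineSVM:
    def test_penalty_grid(self):
        grid = svm_penalty_grid()
        assert len(grid) == 12
        assert grid[0] == 2.0**-3 and grid[-1] == 2.0**8

    def test_separable(self, cheap_sequences, cheap_bundle):
        acc = baseline_svm(cheap_sequences, cheap_bundle.labels, seed=0)
        assert acc >= 0.95

    def test_shuffled_chance(self, cheap_sequences, cheap_bundle):
        rng = np.random.default_rng(5)
        acc = baseline_svm(cheap_sequences,
                           rng.permutation(cheap_bundle.labels), seed=0)
        assert abs(acc - 0.5) <= 0.15

    def test_single_class_rejected(self, cheap_sequences):
        with pytest.raises(ValidationError):
            baseline_svm(cheap_sequences[:10], np.zeros(10, dtype=int))


def test_no_leakage_standardization(cheap_bundle, cheap_sequences):
    """Standardization statistics must come from the training fold only."""
    spec = small_netspec(epochs=1)
    sub = np.arange(40)
    x = cheap_sequences[sub].copy()
    y = cheap_bundle.labels[sub]
    # poison the last 10 trials (the would-be test fold) with a huge offset;
    # a model trained on the first 30 must be unaffected by it
    net = build_network(spec)
    trained = train(net, x[:30], y[:30], spec)
    mean_before = trained.feature_mean.copy()
    x_poisoned = x.copy()
    x_poisoned[30:] += 1e6
    net2 = build_network(spec)
    trained2 = train(net2, x_poisoned[:30], y[:30], spec)
    np.testing.assert_array_equal(trained2.feature_mean, mean_before)
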