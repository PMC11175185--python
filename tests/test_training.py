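"""Training-loop, schedule, loss and evaluation tests (micro-scale models)."""

import numpy as np
import pytest

from emgfusion.model import build_dual_stream, desk_spec
from emgfusion.preprocessing import WindowSpec
from emgfusion.synthetic import SyntheticConfig, generate_dataset
from emgfusion.training import (
    EvalReport,
    TrainConfig,
    aggregate_trial,
    cross_entropy_loss,
    evaluate,
    fit_trial_normalizer,
    lr_schedule,
    paper_scale_config,
    prepare_inputs,
    run_subject_wise,
    train,
)

MICRO_CLASSES = 3


@pytest.fixture(scope="module")
def micro_spec():
    # 1-s trials at 100 Hz -> 5 windows of 20 samples
    return desk_spec(n_classes=MICRO_CLASSES, n_windows=5, window_samples=20,
                     n_channels=4, conv_filters=8, raw_inner_units=8,
                     bilstm_units_per_direction=6, dense_units=16,
                     conv_dropout=0.0, dense_dropout=0.0, l2_coefficient=0.0)


@pytest.fixture(scope="module")
def micro_data():
    config = SyntheticConfig(n_classes=MICRO_CLASSES, n_repetitions=10,
                             n_channels=4, active_duration=1.0,
                             rest_duration=0.5, seed=11)
    train_trials, val_trials = generate_dataset(config, 1,
                                                (set(range(1, 9)), {9, 10}))
    wspec = WindowSpec.from_ms(200.0, fs=100.0, nt=100)
    stats = fit_trial_normalizer(train_trials)
    return (prepare_inputs(train_trials, wspec, stats=stats),
            prepare_inputs(val_trials, wspec, stats=stats))


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        y = np.eye(4)
        assert cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_over_52_classes(self):
        probs = np.full((1, 52), 1 / 52)
        onehot = np.zeros((1, 52))
        onehot[0, 17] = 1
        assert cross_entropy_loss(probs, onehot) == pytest.approx(np.log(52))
        assert cross_entropy_loss(probs, onehot) == pytest.approx(3.9512, abs=1e-4)

    def test_batch_mean(self):
        probs = np.vstack([np.eye(52)[3], np.full(52, 1 / 52)])
        onehot = np.vstack([np.eye(52)[3], np.eye(52)[10]])
        assert cross_entropy_loss(probs, onehot) == pytest.approx(np.log(52) / 2)

    def test_nonnegative(self, rng):
        logits = rng.random((20, 5))
        probs = logits / logits.sum(axis=1, keepdims=True)
        onehot = np.eye(5)[rng.integers(0, 5, 20)]
        assert cross_entropy_loss(probs, onehot) >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.ones((2, 3)), np.ones((3, 2)))


class TestLrSchedule:
    def test_published_settings(self):
        config = TrainConfig()
        assert lr_schedule(0, config) == pytest.approx(1e-4)
        assert lr_schedule(69, config) == pytest.approx(1e-4)
        assert lr_schedule(70, config) == pytest.approx(1e-5)
        assert lr_schedule(400, config) == pytest.approx(1e-5)

    def test_repeated_drop_mode(self):
        config = TrainConfig(repeated_drops=True)
        assert lr_schedule(69, config) == pytest.approx(1e-4)
        assert lr_schedule(70, config) == pytest.approx(1e-5)
        assert lr_schedule(140, config) == pytest.approx(1e-6)

    def test_unit_factor_constant(self):
        config = TrainConfig(lr_drop_factor=1.0)
        assert lr_schedule(500, config) == config.base_lr

    def test_monotone_non_increasing(self):
        config = TrainConfig(repeated_drops=True)
        rates = [lr_schedule(e, config) for e in range(300)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_drop_factor=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)

    def test_paper_scale_config_preserved(self):
        config = paper_scale_config()
        assert config.epochs == 500
        assert config.base_lr == pytest.approx(1e-4)
        assert config.batch_size == 64
        assert (config.beta1, config.beta2) == (0.9, 0.999)


class TestAggregateTrial:
    def test_unanimous(self):
        probs = np.tile(np.eye(10)[7], (25, 1))
        assert aggregate_trial(probs) == 7

    def test_majority_mean(self):
        row2 = np.zeros(12); row2[2] = 0.9; row2[9] = 0.1
        row9 = np.zeros(12); row9[9] = 0.9; row9[2] = 0.1
        probs = np.vstack([np.tile(row2, (13, 1)), np.tile(row9, (12, 1))])
        assert aggregate_trial(probs) == 2

    def test_tie_goes_to_lower_index(self):
        probs = np.array([[0.5, 0.5, 0.0]])
        assert aggregate_trial(probs) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_trial(np.zeros((0, 5)))


class TestTrainLoop:
    def test_empty_training_set_rejected(self, micro_spec):
        graph = build_dual_stream(micro_spec, seed=0)
        with pytest.raises(ValueError):
            train(graph, [], [], TrainConfig(epochs=1))

    def test_loss_descends(self, micro_spec, micro_data):
        train_inputs, _ = micro_data
        graph = build_dual_stream(micro_spec, seed=0)
        config = TrainConfig(epochs=10, base_lr=1e-3, seed=0)
        _, history = train(graph, train_inputs, [], config)
        assert history["train_loss"][9] < history["train_loss"][0]

    def test_single_batch_overfit(self, micro_spec, micro_data):
        train_inputs, _ = micro_data
        subset = train_inputs[:8]
        graph = build_dual_stream(micro_spec, seed=1)
        config = TrainConfig(epochs=200, base_lr=3e-3, seed=1,
                             lr_drop_epoch=1000)
        _, history = train(graph, subset, [], config)
        assert history["train_window_accuracy"][-1] == pytest.approx(100.0)

    def test_seeded_reproducibility(self, micro_spec, micro_data):
        train_inputs, val_inputs = micro_data
        results = []
        for _ in range(2):
            graph = build_dual_stream(micro_spec, seed=3)
            _, history = train(graph, train_inputs, val_inputs,
                               TrainConfig(epochs=3, base_lr=1e-3, seed=3))
            results.append(history["train_loss"])
        np.testing.assert_array_equal(results[0], results[1])

    def test_history_records_schedule(self, micro_spec, micro_data):
        train_inputs, _ = micro_data
        graph = build_dual_stream(micro_spec, seed=0)
        config = TrainConfig(epochs=4, base_lr=1e-3, lr_drop_epoch=2,
                             lr_drop_factor=0.5, seed=0)
        _, history = train(graph, train_inputs, [], config)
        assert history["lr"] == [1e-3, 1e-3, 5e-4, 5e-4]


class TestEvaluate:
    def _graph(self, micro_spec, micro_data, epochs=6):
        train_inputs, val_inputs = micro_data
        graph = build_dual_stream(micro_spec, seed=0)
        graph, _ = train(graph, train_inputs, val_inputs,
                         TrainConfig(epochs=epochs, base_lr=1e-3, seed=0))
        return graph

    def test_report_invariants(self, micro_spec, micro_data):
        train_inputs, val_inputs = micro_data
        graph = self._graph(micro_spec, micro_data)
        report = evaluate(graph, val_inputs)
        assert report.confusion.sum() == report.n_trials == len(val_inputs)
        # per-class accuracy = diagonal / row sums
        for i in range(MICRO_CLASSES):
            row = report.confusion[i].sum()
            if row:
                assert report.per_class_accuracy[i] == pytest.approx(
                    100.0 * report.confusion[i, i] / row)
        # overall accuracy equals count-weighted mean of per-class accuracies
        rows = report.confusion.sum(axis=1)
        present = rows > 0
        weighted = np.nansum(report.per_class_accuracy[present]
                             * rows[present]) / rows.sum()
        assert report.overall_accuracy == pytest.approx(weighted)

    def test_prediction_shape_and_determinism(self, micro_spec, micro_data):
        from emgfusion.training import predict_trial

        _, val_inputs = micro_data
        graph = build_dual_stream(micro_spec, seed=0)
        probs = predict_trial(graph, val_inputs[0])
        assert probs.shape == (5, MICRO_CLASSES)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(probs, predict_trial(graph, val_inputs[0]))

    def test_manual_accuracy_example(self):
        # 3 of 4 correct -> 75%
        confusion = np.array([[2, 0], [1, 1]])
        assert 100.0 * np.trace(confusion) / confusion.sum() == 75.0
        report = EvalReport(overall_accuracy=75.0,
                            per_class_accuracy=np.array([100.0, 50.0]),
                            confusion=confusion, n_trials=4)
        assert report.confusion.sum() == report.n_trials

    def test_confusion_exports(self, micro_spec, micro_data, tmp_path):
        _, val_inputs = micro_data
        graph = build_dual_stream(micro_spec, seed=0)
        report = evaluate(graph, val_inputs)
        csv_path = tmp_path / "confusion.csv"
        report.confusion_to_csv(csv_path)
        loaded = np.loadtxt(csv_path, delimiter=",", dtype=int, ndmin=2)
        np.testing.assert_array_equal(loaded, report.confusion)
        png_path = tmp_path / "confusion.png"
        report.confusion_heatmap(png_path)
        assert png_path.stat().st_size > 0

    def test_empty_evaluation_rejected(self, micro_spec):
        graph = build_dual_stream(micro_spec, seed=0)
        with pytest.raises(ValueError):
            evaluate(graph, [])


class TestSubjectWise:
    def test_identical_subjects_equal_accuracy(self, micro_spec, micro_data):
        train_inputs_unused, _ = micro_data
        config = SyntheticConfig(n_classes=MICRO_CLASSES, n_repetitions=6,
                                 n_channels=4, active_duration=1.0,
                                 rest_duration=0.5, seed=21)
        tr, va = generate_dataset(config, 1, ({1, 2, 3, 4}, {5, 6}))
        wspec = WindowSpec.from_ms(200.0, fs=100.0, nt=100)
        datasets = {0: (tr, va), 1: (list(tr), list(va))}
        reports, mean_acc = run_subject_wise(
            datasets, micro_spec, wspec, TrainConfig(epochs=2, base_lr=1e-3,
                                                     seed=5))
        accs = [reports[0].overall_accuracy, reports[1].overall_accuracy]
        assert accs[0] == accs[1]
        assert mean_acc == pytest.approx(np.mean(accs))

    def test_subject_without_validation_skipped(self, micro_spec):
        config = SyntheticConfig(n_classes=MICRO_CLASSES, n_repetitions=4,
                                 n_channels=4, active_duration=1.0,
                                 rest_duration=0.5, seed=22)
        tr, va = generate_dataset(config, 1, ({1, 2, 3}, {4}))
        wspec = WindowSpec.from_ms(200.0, fs=100.0, nt=100)
        datasets = {0: (tr, va), 1: (tr, [])}
        with pytest.warns(UserWarning, match="subject 1"):
            reports, _ = run_subject_wise(datasets, micro_spec, wspec,
                                          TrainConfig(epochs=1, base_lr=1e-3,
                                                      seed=5))
        assert sorted(reports) == [0]
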