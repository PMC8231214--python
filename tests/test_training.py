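import numpy as np
import pandas as pd
import pytest

from collarcnn.architecture import ArchitectureSpec, ConvBlockSpec, build_model
from collarcnn.preprocessing import FoldPlan, make_folds
from collarcnn.training import (
    BehaviourCNN,
    LeakageError,
    SearchSpace,
    TrainConfig,
    cross_validate,
    evaluate,
    hyperparameter_search,
    train,
    window_length_study,
)
from conftest import make_windowset

# small architecture for fast training tests (receptive field 22 samples)
TINY = ArchitectureSpec.default(
    n_filters=8, expansion=16, n_feature_blocks=2, kernel_size=8, stride=2,
    dropout_p=0.1,
)


def tiny_config(**kwargs):
    defaults = dict(
        seed=0, batch_size=32, max_epochs=15, early_stop_patience=14,
        learning_rate=1e-3,
    )
    defaults.update(kwargs)
    return TrainConfig(**defaults)


class TestTrainContracts:
    def test_animal_overlap_rejected(self):
        ws = make_windowset(2, ["a", "b"])
        net = build_model(TINY, seed=0)
        with pytest.raises(LeakageError):
            train(net, ws.subset_animals(["a", "b"]), ws.subset_animals(["b"]), tiny_config())

    def test_empty_set_rejected(self):
        ws = make_windowset(2, ["a"])
        net = build_model(TINY, seed=0)
        empty = ws.subset_animals([])
        with pytest.raises(ValueError):
            train(net, ws, empty, tiny_config())

    def test_separable_classes_learned(self):
        train_ws = make_windowset(12, ["a", "b", "c"], seed=1)
        val_ws = make_windowset(8, ["d"], seed=2)
        net = build_model(TINY, seed=0)
        net, history = train(net, train_ws, val_ws, tiny_config())
        # loss decreases over the first epochs and the easy task is solved
        assert history["train_loss"].iloc[3] < history["train_loss"].iloc[0]
        report = evaluate(net, val_ws)
        x, y = val_ws.to_arrays()
        accuracy = np.mean(net.predict(x) == y)
        assert accuracy > 0.95
        assert report.macro_f1 > 0.9

    def test_plateau_stops_after_patience_epochs(self):
        # effectively frozen model: vanishing learning rate, so the
        # validation loss never improves after the first epoch
        train_ws = make_windowset(4, ["a"], seed=1)
        val_ws = make_windowset(4, ["b"], seed=2)
        config = tiny_config(
            learning_rate=1e-30, max_epochs=30, early_stop_patience=3,
        )
        net = build_model(TINY, seed=0)
        _, history = train(net, train_ws, val_ws, config)
        assert len(history) == config.early_stop_patience + 1

    def test_seeded_determinism(self):
        train_ws = make_windowset(4, ["a", "b"], seed=1)
        val_ws = make_windowset(4, ["c"], seed=2)
        config = tiny_config(max_epochs=3, early_stop_patience=2)
        state = []
        for _ in range(2):
            net = build_model(TINY, seed=0)
            net, _ = train(net, train_ws, val_ws, config)
            state.append(net.state_dict())
        for key in state[0]:
            assert np.array_equal(state[0][key], state[1][key]), key

    def test_history_records_lr_and_losses(self):
        train_ws = make_windowset(4, ["a"], seed=1)
        val_ws = make_windowset(4, ["b"], seed=2)
        net = build_model(TINY, seed=0)
        _, history = train(net, train_ws, val_ws, tiny_config(max_epochs=4, early_stop_patience=3))
        assert {"epoch", "train_loss", "val_loss", "lr"} <= set(history.columns)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=50, max_epochs=50)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestBehaviourCNNResults:
    def test_fit_returns_results_object(self):
        model = BehaviourCNN(TINY, tiny_config(max_epochs=4, early_stop_patience=3))
        result = model.fit(make_windowset(6, ["a", "b"], seed=1), make_windowset(4, ["c"], seed=2))
        assert result.history.shape[0] >= 1
        assert 0.0 <= result.val_report.macro_f1 <= 1.0
        text = result.summary()
        assert "trainable params" in text and "macro" in text

    def test_predict_shape(self):
        model = BehaviourCNN(TINY, tiny_config(max_epochs=2, early_stop_patience=1))
        result = model.fit(make_windowset(4, ["a"], seed=1), make_windowset(3, ["b"], seed=2))
        ws = make_windowset(2, ["z"], seed=3)
        assert result.predict(ws).shape == (len(ws),)


class TestCrossValidate:
    def test_each_animal_validated_once(self):
        animals = [f"s{i:02d}" for i in range(15)]
        ws = make_windowset(3, animals, seed=1)
        plan = make_folds(animals, k=5, seed=0)
        result = cross_validate(ws, plan, TINY, tiny_config(max_epochs=2, early_stop_patience=1))
        assert len(result.fold_reports) == 5
        validated = [a for fold in plan.folds for a in fold]
        assert sorted(validated) == sorted(animals)
        assert result.scores.shape == (5, 3)

    def test_degenerate_single_fold_rejected(self):
        ws = make_windowset(2, ["a", "b"], seed=1)
        plan = FoldPlan(folds=[["a", "b"]], seed=0)
        with pytest.raises(ValueError):
            cross_validate(ws, plan, TINY, tiny_config())

    def test_unknown_animal_in_plan_rejected(self):
        ws = make_windowset(2, ["a", "b"], seed=1)
        plan = FoldPlan(folds=[["a"], ["ghost"]], seed=0)
        with pytest.raises(ValueError):
            cross_validate(ws, plan, TINY, tiny_config())

    def test_metrics_invariant_to_order_preserving_relabelling(self):
        animals = ["s0", "s1", "s2", "s3"]
        renamed = ["t0", "t1", "t2", "t3"]  # preserves lexicographic order
        ws_a = make_windowset(3, animals, seed=1)
        ws_b = make_windowset(3, renamed, seed=1)
        config = tiny_config(max_epochs=2, early_stop_patience=1)
        plan_a = FoldPlan(folds=[["s0", "s1"], ["s2", "s3"]], seed=0)
        plan_b = FoldPlan(folds=[["t0", "t1"], ["t2", "t3"]], seed=0)
        res_a = cross_validate(ws_a, plan_a, TINY, config)
        res_b = cross_validate(ws_b, plan_b, TINY, config)
        pd.testing.assert_frame_equal(res_a.scores, res_b.scores)

    def test_summary_text(self):
        ws = make_windowset(3, ["a", "b", "c", "d"], seed=1)
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        result = cross_validate(ws, plan, TINY, tiny_config(max_epochs=2, early_stop_patience=1))
        assert "cross-validation" in result.summary()


class TestHyperparameterSearch:
    def test_single_point_space_returns_it(self):
        space = SearchSpace(n_blocks=(3,), kernel_sizes=(8,), dropout_ps=(0.1,), repeats=1)
        ws = make_windowset(3, ["a", "b", "c", "d"], seed=1)
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        best, table = hyperparameter_search(
            space, ws, plan, tiny_config(max_epochs=2, early_stop_patience=1),
            n_filters=8, expansion=16,
        )
        assert best.dropout_p == 0.1
        assert len(best.conv_blocks) == 3

    def test_table_has_grid_times_repeats_times_folds_rows(self):
        space = SearchSpace(n_blocks=(2, 3), kernel_sizes=(8,), dropout_ps=(0.1,), repeats=2)
        ws = make_windowset(3, ["a", "b", "c", "d"], seed=1)
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        _, table = hyperparameter_search(
            space, ws, plan, tiny_config(max_epochs=2, early_stop_patience=1),
            n_filters=8, expansion=16,
        )
        assert len(table) == 2 * 2 * 2

    def test_informative_kernel_beats_pointwise(self):
        # classes share amplitude and differ only in frequency, so a
        # kernel-1-everywhere network has nothing to detect
        ws = make_windowset(
            10, ["a", "b", "c", "d"], seed=3,
            amplitude_by_class=(1.0, 1.0, 1.0), freq_by_class=(0.4, 1.2, 3.2),
        )
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        space = SearchSpace(n_blocks=(2, 3), kernel_sizes=(1, 8), dropout_ps=(0.1,), repeats=1)
        best, table = hyperparameter_search(
            space, ws, plan, tiny_config(), n_filters=8, expansion=16,
        )
        assert best.conv_blocks[0].kernel_size == 8
        grouped = table.groupby("kernel_size")["f1"].mean()
        assert grouped[8] > grouped[1]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(n_blocks=())


class TestWindowLengthStudy:
    def _windows_by_length(self):
        animals = ["a", "b", "c", "d"]
        return {
            sec: make_windowset(3, animals, length=int(sec * 10), seed=2)
            for sec in (3.0, 4.5, 6.0)
        }

    def test_all_nine_cells_populated(self):
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        matrix, intervals = window_length_study(
            self._windows_by_length(), plan, TINY,
            tiny_config(max_epochs=2, early_stop_patience=1), ci_resamples=200,
        )
        assert matrix.shape == (3, 3)
        assert matrix.notna().all().all()
        assert ((matrix >= 0) & (matrix <= 1)).all().all()
        assert set(intervals) == {(a, b) for a in (3.0, 4.5, 6.0) for b in (3.0, 4.5, 6.0)}
        for low, high in intervals.values():
            assert low <= high

    def test_windows_below_receptive_field_rejected(self):
        plan = FoldPlan(folds=[["a", "b"], ["c", "d"]], seed=0)
        short = {1.0: make_windowset(2, ["a", "b", "c", "d"], length=10, seed=2)}
        with pytest.raises(ValueError, match="receptive field"):
            window_length_study(short, plan, TINY, tiny_config())
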