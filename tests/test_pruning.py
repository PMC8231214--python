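import numpy as np
import pytest

from collarcnn.architecture import ArchitectureSpec, build_model, count_params
from collarcnn.nn import BatchNorm1d, Conv1d, Linear
from collarcnn.pruning import (
    PruneConfig,
    StructuralError,
    prune_stage,
    rank_filters_l1,
    remove_filters,
    run_pruning,
    target_sparsity,
    to_half_precision,
)

CFG = PruneConfig()  # s_f=0.5, n=35, dt=1


class TestTargetSparsity:
    def test_zero_at_start(self):
        assert target_sparsity(0, CFG) == 0.0

    def test_final_sparsity_at_horizon(self):
        assert target_sparsity(35, CFG) == pytest.approx(0.5)

    def test_hand_evaluated_midpoint(self):
        # 0.5 - 0.5 * (1 - 7/35)^3 = 0.5 - 0.5 * 0.8^3 = 0.244
        assert target_sparsity(7, CFG) == pytest.approx(0.244)

    def test_monotone_non_decreasing(self):
        values = [target_sparsity(t, CFG) for t in range(0, 36)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_off_grid_rejected(self):
        cfg = PruneConfig(delta_t=5, n=7)
        with pytest.raises(ValueError):
            target_sparsity(3, cfg)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            target_sparsity(36, CFG)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PruneConfig(s_f=0.0)
        with pytest.raises(ValueError):
            PruneConfig(n=0)


class TestRankFilters:
    def test_hand_ordering(self):
        w = np.zeros((3, 1, 1))
        w[0, 0, 0], w[1, 0, 0], w[2, 0, 0] = 0.5, 0.1, 0.3
        assert rank_filters_l1(w).tolist() == [1, 2, 0]

    def test_ties_stable(self):
        w = np.ones((4, 2, 3))
        assert rank_filters_l1(w).tolist() == [0, 1, 2, 3]

    def test_single_filter(self):
        assert rank_filters_l1(np.ones((1, 2, 3))).tolist() == [0]

    def test_bias_is_not_part_of_importance(self, rng):
        # ranking reads only the weight tensor; build a conv where bias
        # would invert the order if it were included
        net = build_model(ArchitectureSpec.default(n_filters=4, expansion=8), seed=0)
        conv = net.conv_layers[0]
        conv.params["weight"][:] = 0
        conv.params["weight"][0] += 0.01   # smallest weight norm
        conv.params["weight"][1] += 1.0
        conv.params["weight"][2] += 2.0
        conv.params["weight"][3] += 3.0
        conv.params["bias"][:] = [100.0, 0.0, 0.0, 0.0]
        assert rank_filters_l1(conv.params["weight"]).tolist() == [0, 1, 2, 3]


def _tiny_spec():
    return ArchitectureSpec.default(
        n_filters=6, expansion=10, n_feature_blocks=2, kernel_size=4, stride=2,
        dropout_p=0.0,
    )


class TestRemoveFilters:
    def test_empty_removal_identity(self, rng):
        net = build_model(_tiny_spec(), seed=1)
        x = rng.standard_normal((3, 3, 40)).astype(np.float32)
        before = net.forward(x)
        after = remove_filters(net, {}).forward(x)
        assert np.allclose(before, after)

    def test_matches_zero_channel_oracle(self, rng):
        net = build_model(_tiny_spec(), seed=2)
        x = rng.standard_normal((4, 3, 40)).astype(np.float32)
        removals = {0: [1, 4], 1: [0], 2: [2, 3, 7]}
        pruned_out = remove_filters(net, removals).forward(x)

        # oracle: zero the removed channels' conv output and batch-norm
        # contribution in the full network
        clone = build_model(_tiny_spec(), seed=2)
        for b, idx in removals.items():
            conv, bn = clone.conv_layers[b], clone.batchnorm_layers[b]
            conv.params["weight"][idx] = 0
            conv.params["bias"][list(idx)] = 0
            bn.params["weight"][list(idx)] = 0
            bn.params["bias"][list(idx)] = 0
            bn.running_mean[list(idx)] = 0
        zeroed_out = clone.forward(x)
        assert np.allclose(pruned_out, zeroed_out, atol=1e-5)

    def test_surviving_weights_bit_exact(self):
        net = build_model(_tiny_spec(), seed=3)
        keep = [2, 3, 5]
        pruned = remove_filters(net, {0: [0, 1, 4]})
        assert np.array_equal(
            pruned.conv_layers[0].params["weight"],
            net.conv_layers[0].params["weight"][keep],
        )
        assert np.array_equal(
            pruned.conv_layers[1].params["weight"],
            net.conv_layers[1].params["weight"][:, keep, :],
        )

    def test_head_columns_follow_last_block(self):
        net = build_model(_tiny_spec(), seed=4)
        pruned = remove_filters(net, {2: [0, 9]})
        assert np.array_equal(
            pruned.head.params["weight"], net.head.params["weight"][:, 1:9]
        )

    def test_param_count_matches_spec_accounting(self):
        net = build_model(_tiny_spec(), seed=5)
        pruned = remove_filters(net, {0: [0], 1: [1, 2], 2: [0, 1, 2]})
        assert pruned.n_trainable_parameters() == count_params(pruned.spec)

    def test_cannot_remove_all_filters(self):
        net = build_model(_tiny_spec(), seed=6)
        with pytest.raises(StructuralError):
            remove_filters(net, {0: list(range(6))})

    def test_out_of_range_index_rejected(self):
        net = build_model(_tiny_spec(), seed=6)
        with pytest.raises(ValueError):
            remove_filters(net, {0: [99]})


class TestPruneStage:
    def test_first_stage_halves_reference_blocks(self):
        net = build_model(ArchitectureSpec.default(), seed=0)
        net, frame = prune_stage(net, CFG)  # surgery-only
        assert [c.out_channels for c in net.conv_layers] == [32, 32, 32, 256]
        assert frame["sparsity"].iloc[-1] == pytest.approx(0.5)

    def test_four_stage_trajectory_reaches_reference_counts(self):
        net = build_model(ArchitectureSpec.default(), seed=0)
        net, trajectory = run_pruning(net, CFG)
        stages = trajectory.stages
        assert list(stages["filters"]) == [
            (32, 32, 32, 256),
            (16, 16, 16, 128),
            (8, 8, 8, 64),
            (4, 4, 4, 32),
        ]
        assert stages["params"].iloc[-1] == 1_063
        assert stages["params"].iloc[1] == 11_923

    def test_cumulative_removals_track_schedule_within_rounding(self):
        net = build_model(ArchitectureSpec.default(), seed=0)
        _, frame = prune_stage(net, CFG)
        for _, row in frame.iterrows():
            expected = 64 - round(row["sparsity"] * 64)
            assert abs(row["filters"][0] - expected) <= 1

    def test_filters_non_increasing_across_iterations(self):
        net = build_model(ArchitectureSpec.default(n_filters=16, expansion=32), seed=1)
        _, frame = prune_stage(net, PruneConfig(n=10))
        counts = [f[0] for f in frame["filters"]]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_param_counts_match_spec_throughout(self):
        net = build_model(ArchitectureSpec.default(n_filters=8, expansion=16), seed=1)
        net, frame = prune_stage(net, PruneConfig(n=5))
        assert net.n_trainable_parameters() == frame["params"].iloc[-1]


class TestHalfPrecision:
    def _trained_like_net(self):
        net = build_model(_tiny_spec(), seed=7)
        rng = np.random.default_rng(0)
        # give batch-norm non-trivial statistics so eval mode is exercised
        for _ in range(5):
            net.forward(rng.standard_normal((8, 3, 40)).astype(np.float32), training=True, rng=rng)
        return net

    def test_batchnorm_stays_fp32(self):
        half = to_half_precision(self._trained_like_net())
        for layer in half.layers:
            if isinstance(layer, BatchNorm1d):
                assert layer.params["weight"].dtype == np.float32
                assert layer.running_mean.dtype == np.float32
            elif isinstance(layer, (Conv1d, Linear)):
                assert all(p.dtype == np.float16 for p in layer.params.values())

    def test_predictions_match_fp32(self, rng):
        net = self._trained_like_net()
        half = to_half_precision(net)
        x = rng.standard_normal((500, 3, 40)).astype(np.float32)
        agreement = np.mean(net.predict(x) == half.predict(x))
        assert agreement >= 0.99

    def test_source_model_unmodified(self):
        net = self._trained_like_net()
        to_half_precision(net)
        assert net.conv_layers[0].params["weight"].dtype == np.float32
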