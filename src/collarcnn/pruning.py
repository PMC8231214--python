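"""Multi-stage structured filter pruning with a cubic sparsity schedule.

Within a pruning stage, the cumulative fraction of filters removed follows

    s_t = s_f - s_f * (1 - t / (n * dt))**3,   t in {0, dt, ..., n*dt}

so pruning is aggressive early (when many redundant filters exist) and
asymptotically gentle as the stage approaches its final sparsity ``s_f``
(0.5 per stage in the reference configuration: four stages take 64-filter
blocks to 32, 16, 8 and then 4 filters, with the expansion block pruned at
the same fractional schedule and the head input shrinking accordingly).

Filter importance is the l1 norm of the filter's weights (bias excluded);
the lowest-norm filters go first, re-ranked at every pruning iteration.
Removal is *structural*: the filter's outgoing weights, bias and batch-norm
parameters are deleted together with the corresponding incoming-channel
slices of the next convolution (or of the head after the expansion block),
and surviving weights are preserved bit-exactly. Training continues between
pruning iterations at a constant learning rate; each stage ends with a
fine-tuning phase under the one-cycle policy.

Half-precision reduction casts convolution and head weights to FP16 while
batch-norm parameters stay FP32 for numerical stability; arithmetic is
performed in FP32 either way, so FP16 here is a storage format, as it would
be on the target micro-controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .architecture import ArchitectureSpec, build_model, count_params
from .nn import AdamW, ConstantSchedule, Conv1d, ConvNet, softmax_cross_entropy
from .preprocessing import WindowSet
from .training import TrainConfig, evaluate, train

__all__ = [
    "PruneConfig",
    "PruneTrajectory",
    "target_sparsity",
    "rank_filters_l1",
    "remove_filters",
    "prune_stage",
    "run_pruning",
    "to_half_precision",
]


class StructuralError(ValueError):
    """A surgery request would leave a block with no filters."""


@dataclass(frozen=True)
class PruneConfig:
    """Schedule symbols: final per-stage sparsity ``s_f``, iterations per
    stage ``n`` (one per epoch), pruning frequency ``delta_t`` in epochs."""

    s_f: float = 0.5
    n: int = 35
    delta_t: int = 1
    stages: int = 4
    fine_tune_epochs: int = 15
    prune_lr: float = 1e-4

    def __post_init__(self):
        if not 0.0 < self.s_f <= 1.0:
            raise ValueError("s_f must be in (0, 1]")
        if self.n < 1 or self.delta_t < 1 or self.stages < 1:
            raise ValueError("n, delta_t and stages must be >= 1")
        if self.fine_tune_epochs < 0:
            raise ValueError("fine_tune_epochs must be >= 0")


def target_sparsity(t: int, cfg: PruneConfig) -> float:
    """Cumulative sparsity at iteration ``t``: monotone non-decreasing, 0 at
    t=0 and exactly ``s_f`` at t = n * delta_t."""
    horizon = cfg.n * cfg.delta_t
    if t < 0 or t > horizon:
        raise ValueError(f"t={t} outside the schedule range [0, {horizon}]")
    if t % cfg.delta_t != 0:
        raise ValueError(f"t={t} is not a multiple of delta_t={cfg.delta_t}")
    return cfg.s_f - cfg.s_f * (1.0 - t / horizon) ** 3


def rank_filters_l1(conv_weight: np.ndarray) -> np.ndarray:
    """Filter indices ordered by ascending l1 norm (sum of absolute weights,
    bias excluded); ties keep the lower index first (stable sort)."""
    w = np.asarray(conv_weight)
    if w.ndim != 3 or w.shape[0] < 1:
        raise ValueError("expected a conv weight of shape (out, in, kernel)")
    norms = np.abs(w.astype(np.float64)).sum(axis=(1, 2))
    return np.argsort(norms, kind="stable")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def remove_filters(net: ConvNet, removals: dict[int, "set[int] | list[int]"]) -> ConvNet:
    """Return a structurally smaller network with the given per-block filter
    index sets removed.

    For block ``i`` the removed filters' conv rows, biases and batch-norm
    parameters (and running statistics) are deleted, along with the matching
    incoming-channel slices of block ``i+1`` — or of the head when ``i`` is
    the last block. Surviving weights are copied bit-exactly; nothing is
    re-initialised.
    """
    spec: ArchitectureSpec = net.spec
    convs = net.conv_layers
    bns = net.batchnorm_layers
    n_blocks = len(convs)

    keep: list[np.ndarray] = []
    for i in range(n_blocks):
        out_ch = convs[i].out_channels
        drop = set(int(j) for j in removals.get(i, ()))
        bad = [j for j in drop if not 0 <= j < out_ch]
        if bad:
            raise ValueError(f"block {i}: filter indices {bad} out of range 0..{out_ch - 1}")
        kept = np.array([j for j in range(out_ch) if j not in drop], dtype=np.intp)
        if kept.size == 0:
            raise StructuralError(f"cannot prune all {out_ch} filters of block {i}")
        keep.append(kept)

    new_spec = spec.with_filters([k.size for k in keep])
    new_net = build_model(new_spec, seed=0)
    new_convs = new_net.conv_layers
    new_bns = new_net.batchnorm_layers

    for i in range(n_blocks):
        in_keep = keep[i - 1] if i > 0 else np.arange(spec.in_channels, dtype=np.intp)
        w = convs[i].params["weight"][keep[i]][:, in_keep, :]
        new_convs[i].params["weight"] = w.copy()
        new_convs[i].params["bias"] = convs[i].params["bias"][keep[i]].copy()
        new_bns[i].params["weight"] = bns[i].params["weight"][keep[i]].copy()
        new_bns[i].params["bias"] = bns[i].params["bias"][keep[i]].copy()
        new_bns[i].running_mean = bns[i].running_mean[keep[i]].copy()
        new_bns[i].running_var = bns[i].running_var[keep[i]].copy()
    new_net.head.params["weight"] = net.head.params["weight"][:, keep[-1]].copy()
    new_net.head.params["bias"] = net.head.params["bias"].copy()
    return new_net


def _train_epochs(
    net: ConvNet,
    train_ws: WindowSet,
    epochs: int,
    lr: float,
    weight_decay: float,
    batch_size: int,
    rng: np.random.Generator,
) -> None:
    """Plain constant-rate training epochs (the between-iterations regime)."""
    x, y = train_ws.to_arrays()
    optimiser = AdamW(net, lr=lr, weight_decay=weight_decay)
    schedule = ConstantSchedule(lr)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(x.shape[0])
        for i in range(0, order.size, batch_size):
            idx = order[i : i + batch_size]
            logits = net.forward(x[idx], training=True, rng=rng)
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            optimiser.step(schedule.lr_at(step))
            step += 1


def prune_stage(
    net: ConvNet,
    cfg: PruneConfig,
    train_ws: WindowSet | None = None,
    val_ws: WindowSet | None = None,
    train_config: TrainConfig | None = None,
    stage_index: int = 0,
) -> tuple[ConvNet, pd.DataFrame]:
    """One pruning stage: iterate the cubic schedule, removing the lowest-l1
    filters per block at each iteration, training between iterations at the
    constant pruning rate, then fine-tune with the one-cycle policy.

    With ``train_ws=None`` the surgery follows the schedule without the
    interleaved optimisation (useful for structural verification); per-stage
    sparsity targets are relative to the stage-initial filter counts, so a
    0.5 stage halves every block. Returns the reduced network and the
    per-iteration trajectory (iteration, sparsity, filters per block,
    parameter count).
    """
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed + 7919 * (stage_index + 1))
    initial = [c.out_channels for c in net.conv_layers]
    removed = [0] * len(initial)
    rows = []
    for t in range(0, cfg.n * cfg.delta_t + 1, cfg.delta_t):
        s_t = target_sparsity(t, cfg)
        removals: dict[int, list[int]] = {}
        for b, n0 in enumerate(initial):
            target_removed = min(_round_half_away(s_t * n0), n0 - 1)
            extra = target_removed - removed[b]
            if extra > 0:
                order = rank_filters_l1(net.conv_layers[b].params["weight"])
                removals[b] = order[:extra].tolist()
                removed[b] += extra
        if removals:
            net = remove_filters(net, removals)
        rows.append(
            {
                "stage": stage_index,
                "iteration": t,
                "sparsity": s_t,
                "filters": tuple(c.out_channels for c in net.conv_layers),
                "params": count_params(net.spec),
            }
        )
        if train_ws is not None and t < cfg.n * cfg.delta_t:
            _train_epochs(
                net,
                train_ws,
                epochs=cfg.delta_t,
                lr=cfg.prune_lr,
                weight_decay=train_config.weight_decay,
                batch_size=train_config.batch_size,
                rng=rng,
            )
    if train_ws is not None and val_ws is not None and cfg.fine_tune_epochs > 0:
        ft_config = dc_replace(
            train_config,
            max_epochs=cfg.fine_tune_epochs,
            early_stop_patience=max(1, cfg.fine_tune_epochs - 1),
            seed=train_config.seed + 7919 * (stage_index + 1) + 1,
        )
        net, _ = train(net, train_ws, val_ws, ft_config)
    return net, pd.DataFrame(rows)


@dataclass
class PruneTrajectory:
    """Stacked per-iteration schedule records plus per-stage summaries."""

    iterations: pd.DataFrame
    stages: pd.DataFrame

    def summary(self) -> str:
        return "Pruning trajectory (per stage)\n" + self.stages.to_string(index=False)


def run_pruning(
    net: ConvNet,
    cfg: PruneConfig,
    train_ws: WindowSet | None = None,
    val_ws: WindowSet | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[ConvNet, PruneTrajectory]:
    """Run ``cfg.stages`` pruning stages; filter counts are non-increasing
    across stages and each stage ends exactly at its target sparsity."""
    iteration_frames = []
    stage_rows = []
    for stage in range(cfg.stages):
        net, frame = prune_stage(
            net, cfg, train_ws=train_ws, val_ws=val_ws,
            train_config=train_config, stage_index=stage,
        )
        iteration_frames.append(frame)
        row = {
            "stage": stage,
            "filters": tuple(c.out_channels for c in net.conv_layers),
            "params": count_params(net.spec),
        }
        if val_ws is not None and train_ws is not None:
            row["val_macro_f1"] = evaluate(net, val_ws).macro_f1
        stage_rows.append(row)
    return net, PruneTrajectory(
        iterations=pd.concat(iteration_frames, ignore_index=True),
        stages=pd.DataFrame(stage_rows),
    )


def to_half_precision(net: ConvNet) -> ConvNet:
    """Copy of the network with convolution and head weights stored as FP16;
    batch-norm parameters (and running statistics) stay FP32. Forward
    arithmetic is FP32 in both variants, so this changes storage only."""
    from .nn import BatchNorm1d, Linear

    clone = build_model(net.spec, seed=0)
    clone.load_state_dict(net.state_dict())
    for layer in clone.layers:
        if isinstance(layer, BatchNorm1d):
            continue
        if isinstance(layer, (Conv1d, Linear)):
            for key in layer.params:
                layer.params[key] = layer.params[key].astype(np.float16)
    return clone
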