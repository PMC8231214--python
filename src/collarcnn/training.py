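"""Training policy, grouped cross-validation and hyper-parameter search.

The policy: AdamW at base learning rate 1e-4 with decoupled weight decay
0.01, batch size 256, a one-cycle learning-rate schedule (warm-up to ten
times the base rate, cosine annealing down), at most 50 epochs with early
stopping when the validation loss fails to improve by 0.01 for 15 epochs;
the returned weights are those of the best-validation-loss epoch.

Cross-validation is grouped by animal: folds partition animal identifiers,
and a hard leakage guard refuses any train/validation pair sharing an
animal. The model surface follows the estimator/results idiom:
``BehaviourCNN(spec, config).fit(train, val)`` returns a
:class:`TrainingResult`; ``cross_validate`` returns a
:class:`CrossValidationResult`; both carry a ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architecture import ArchitectureSpec, build_model
from .evaluation import MetricsReport, bootstrap_ci
from .nn import AdamW, ConvNet, OneCycleSchedule, softmax_cross_entropy
from .preprocessing import FoldPlan, WindowSet, balance_windows

__all__ = [
    "TrainConfig",
    "SearchSpace",
    "LeakageError",
    "train",
    "evaluate",
    "cross_validate",
    "hyperparameter_search",
    "window_length_study",
    "BehaviourCNN",
    "TrainingResult",
    "CrossValidationResult",
]


class LeakageError(ValueError):
    """An animal appears in both the training and validation partitions."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters (defaults are the reference policy)."""

    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 50
    early_stop_patience: int = 15
    early_stop_min_delta: float = 0.01
    weight_decay: float = 0.01
    onecycle_peak_factor: float = 10.0
    onecycle_warmup_frac: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning rate, batch size and max epochs must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _check_disjoint(train_ws: WindowSet, val_ws: WindowSet) -> None:
    if len(train_ws) == 0 or len(val_ws) == 0:
        raise ValueError("training and validation sets must be non-empty")
    overlap = set(train_ws.animal_ids) & set(val_ws.animal_ids)
    if overlap:
        raise LeakageError(f"animal(s) {sorted(overlap)} present in both partitions")


def _epoch_loss(net: ConvNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, x.shape[0], batch_size):
        logits = net.forward(x[i : i + batch_size], training=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss)
        weights.append(len(y[i : i + batch_size]))
    return float(np.average(losses, weights=weights))


def train(
    net: ConvNet,
    train_ws: WindowSet,
    val_ws: WindowSet,
    config: TrainConfig,
) -> tuple[ConvNet, pd.DataFrame]:
    """Fit ``net`` in place; returns it (best-epoch weights restored) and the
    per-epoch history (epoch, train_loss, val_loss, lr)."""
    _check_disjoint(train_ws, val_ws)
    x_train, y_train = train_ws.to_arrays()
    x_val, y_val = val_ws.to_arrays()
    rng = np.random.default_rng(config.seed)

    steps_per_epoch = max(1, int(np.ceil(x_train.shape[0] / config.batch_size)))
    schedule = OneCycleSchedule(
        config.learning_rate,
        total_steps=config.max_epochs * steps_per_epoch,
        peak_factor=config.onecycle_peak_factor,
        warmup_frac=config.onecycle_warmup_frac,
    )
    optimiser = AdamW(net, lr=config.learning_rate, weight_decay=config.weight_decay)

    best_val = np.inf
    best_state = net.state_dict()
    wait = 0
    step = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_train.shape[0])
        batch_losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.forward(x_train[idx], training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            net.backward(dlogits)
            lr = schedule.lr_at(step)
            optimiser.step(lr)
            step += 1
            batch_losses.append(loss)
        val_loss = _epoch_loss(net, x_val, y_val, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
                "lr": schedule.lr_at(step - 1),
            }
        )
        if val_loss < best_val - config.early_stop_min_delta:
            best_val = val_loss
            best_state = net.state_dict()
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    net.load_state_dict(best_state)
    return net, pd.DataFrame(rows)


def evaluate(net: ConvNet, ws: WindowSet, batch_size: int = 256) -> MetricsReport:
    x, y = ws.to_arrays()
    pred = net.predict(x, batch_size=batch_size)
    return MetricsReport.from_labels(y, pred)


@dataclass
class TrainingResult:
    """Fitted-model results: weights, history and validation metrics."""

    net: ConvNet
    spec: ArchitectureSpec
    config: TrainConfig
    history: pd.DataFrame
    val_report: MetricsReport

    def predict(self, ws: WindowSet) -> np.ndarray:
        x, _ = ws.to_arrays()
        return self.net.predict(x)

    def evaluate(self, ws: WindowSet) -> MetricsReport:
        return evaluate(self.net, ws)

    def summary(self) -> str:
        lines = [
            "Behaviour CNN training result",
            f"  epochs run          : {len(self.history)}",
            f"  best validation loss: {self.history['val_loss'].min():.4f}",
            f"  trainable params    : {self.net.n_trainable_parameters():,}",
            "",
            self.val_report.summary(),
        ]
        return "\n".join(lines)


class BehaviourCNN:
    """Estimator wrapper: architecture + training policy; ``fit`` trains on a
    labelled window set and returns a :class:`TrainingResult`."""

    def __init__(self, spec: ArchitectureSpec | None = None, config: TrainConfig | None = None):
        self.spec = spec or ArchitectureSpec.default()
        self.config = config or TrainConfig()

    def build(self) -> ConvNet:
        return build_model(self.spec, seed=self.config.seed)

    def fit(self, train_ws: WindowSet, val_ws: WindowSet) -> TrainingResult:
        net = self.build()
        net, history = train(net, train_ws, val_ws, self.config)
        return TrainingResult(
            net=net,
            spec=self.spec,
            config=self.config,
            history=history,
            val_report=evaluate(net, val_ws),
        )


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    scores: pd.DataFrame  # one row per fold: f1, precision, recall

    @property
    def mean_f1(self) -> float:
        return float(self.scores["f1"].mean())

    @property
    def std_f1(self) -> float:
        return float(self.scores["f1"].std(ddof=1)) if len(self.scores) > 1 else 0.0

    def summary(self) -> str:
        agg = self.scores.agg(["mean", "std"]).round(3)
        return "Grouped cross-validation (macro averages per fold)\n" + agg.to_string()


def cross_validate(
    windows: WindowSet,
    plan: FoldPlan,
    spec: ArchitectureSpec,
    config: TrainConfig,
    balance: bool = True,
) -> CrossValidationResult:
    """Train/validate once per fold: the fold's animals validate, the rest
    train (balanced per animal and class by undersampling)."""
    known = set(windows.animal_ids)
    for fold in plan.folds:
        unknown = set(fold) - known
        if unknown:
            raise ValueError(f"fold references unknown animal(s) {sorted(unknown)}")
    if plan.k < 2:
        raise ValueError("need k >= 2 folds (k=1 leaves no training animals)")

    reports: list[MetricsReport] = []
    rows = []
    for f, fold in enumerate(plan.folds):
        val_animals = set(fold)
        train_animals = [a for a in windows.animal_ids if a not in val_animals]
        train_ws = windows.subset_animals(train_animals)
        val_ws = windows.subset_animals(fold)
        if balance:
            train_ws = balance_windows(train_ws, seed=config.seed + 31 * f)
            val_ws = balance_windows(val_ws, seed=config.seed + 31 * f + 1)
        fold_config = replace(config, seed=config.seed + f)
        net = build_model(spec, seed=fold_config.seed)
        net, _ = train(net, train_ws, val_ws, fold_config)
        report = evaluate(net, val_ws)
        reports.append(report)
        rows.append(
            {
                "fold": f,
                "f1": report.macro_f1,
                "precision": report.macro_precision,
                "recall": report.macro_recall,
            }
        )
    return CrossValidationResult(fold_reports=reports, scores=pd.DataFrame(rows).set_index("fold"))


@dataclass(frozen=True)
class SearchSpace:
    """Hyper-parameter grid: total block counts (the kernel-1 expansion block
    is always retained as the last block), kernel sizes for the feature
    blocks, and dropout probabilities."""

    n_blocks: tuple[int, ...] = (2, 3, 4)
    kernel_sizes: tuple[int, ...] = (8, 16, 32)
    dropout_ps: tuple[float, ...] = (0.1, 0.25, 0.5)
    repeats: int = 5

    def __post_init__(self):
        if not (self.n_blocks and self.kernel_sizes and self.dropout_ps):
            raise ValueError("candidate lists must be non-empty")
        if min(self.n_blocks) < 2:
            raise ValueError("need at least 2 blocks (one feature block + expansion)")

    def specs(self, n_filters: int = 64, expansion: int = 512):
        for nb, k, p in itertools.product(self.n_blocks, self.kernel_sizes, self.dropout_ps):
            yield (nb, k, p), ArchitectureSpec.default(
                n_filters=n_filters,
                expansion=expansion,
                n_feature_blocks=nb - 1,
                kernel_size=k,
                dropout_p=p,
            )


def hyperparameter_search(
    space: SearchSpace,
    windows: WindowSet,
    plan: FoldPlan,
    config: TrainConfig,
    n_filters: int = 64,
    expansion: int = 512,
) -> tuple[ArchitectureSpec, pd.DataFrame]:
    """Full grid x repeats x folds; returns the spec with highest mean macro
    F1 and the full score table (one row per grid point, repeat and fold)."""
    rows = []
    best_spec, best_score = None, -np.inf
    for (nb, k, p), spec in space.specs(n_filters=n_filters, expansion=expansion):
        scores = []
        for r in range(space.repeats):
            sub = replace(config, seed=config.seed + 101 * r)
            result = cross_validate(windows, plan, spec, sub)
            for fold, f1 in result.scores["f1"].items():
                rows.append(
                    {
                        "n_blocks": nb,
                        "kernel_size": k,
                        "dropout_p": p,
                        "repeat": r,
                        "fold": fold,
                        "f1": f1,
                    }
                )
                scores.append(f1)
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score, best_spec = mean, spec
    return best_spec, pd.DataFrame(rows)


def window_length_study(
    windows_by_length: dict[float, WindowSet],
    plan: FoldPlan,
    spec: ArchitectureSpec,
    config: TrainConfig,
    ci_level: float = 0.95,
    ci_resamples: int = 2000,
) -> tuple[pd.DataFrame, dict[tuple[float, float], tuple[float, float]]]:
    """Train at each window length, evaluate at every length (the adaptive
    pooling makes the classifier length-agnostic); returns the mean-F1 matrix
    (rows: training length, columns: evaluation length) and per-cell
    bootstrap confidence intervals over fold scores."""
    lengths = sorted(windows_by_length)
    rf = spec.receptive_field()
    for length in lengths:
        ws = windows_by_length[length]
        if ws.windows and ws.windows[0].data.shape[1] < rf:
            raise ValueError(
                f"{length} s windows shorter than the receptive field ({rf} samples); "
                "cross-length evaluation requires an adaptive architecture that fits "
                "every window length"
            )
    cells: dict[tuple[float, float], list[float]] = {
        (tr, ev): [] for tr in lengths for ev in lengths
    }
    for train_len in lengths:
        train_pool = windows_by_length[train_len]
        for f, fold in enumerate(plan.folds):
            val_animals = set(fold)
            train_animals = [a for a in train_pool.animal_ids if a not in val_animals]
            train_ws = balance_windows(
                train_pool.subset_animals(train_animals), seed=config.seed + 31 * f
            )
            fold_config = replace(config, seed=config.seed + f)
            net = build_model(spec, seed=fold_config.seed)
            val_same = balance_windows(
                train_pool.subset_animals(fold), seed=config.seed + 31 * f + 1
            )
            net, _ = train(net, train_ws, val_same, fold_config)
            for eval_len in lengths:
                val_ws = balance_windows(
                    windows_by_length[eval_len].subset_animals(fold),
                    seed=config.seed + 31 * f + 2,
                )
                cells[(train_len, eval_len)].append(evaluate(net, val_ws).macro_f1)
    matrix = pd.DataFrame(
        [[float(np.mean(cells[(tr, ev)])) for ev in lengths] for tr in lengths],
        index=pd.Index(lengths, name="train_s"),
        columns=pd.Index(lengths, name="eval_s"),
    )
    intervals = {
        key: bootstrap_ci(scores, level=ci_level, resamples=ci_resamples, seed=config.seed)
        for key, scores in cells.items()
    }
    return matrix, intervals
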