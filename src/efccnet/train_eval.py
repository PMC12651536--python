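"""Training, cross-validation, evaluation and ablation harness.

The protocol: a stratified 80/20 train/test split (per class), 10-fold
stratified cross-validation on the training set with Adam + cross-entropy
(learning rate 0.01, batch size 200), fold results reported as mean +/- sd,
the best-accuracy fold model kept for the held-out test evaluation, and
metrics (accuracy, one-vs-rest precision/recall, macro averages) derived
from the confusion matrix.

Ablation grids vary the strip directions, the branch subset, and the
convolution / self-attention / residual components of the EFCM blocks purely
through :class:`~efccnet.network.ModelConfig`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, StratifiedShuffleSplit

from . import _tensor as T
from .efcm import BranchSpec
from .network import EFCCNet, ModelConfig, build_model
from .synthetic import EEGDataset

__all__ = [
    "TrainConfig",
    "Metrics",
    "CVResult",
    "Adam",
    "desk_train_config",
    "stratified_split",
    "train",
    "evaluate",
    "compute_metrics",
    "kfold_cv",
    "select_best_fold",
    "run_ablation",
    "directions_grid",
    "branches_grid",
    "components_grid",
    "channels_grid",
    "efcm_units_grid",
    "GRIDS",
]


@dataclass
class TrainConfig:
    """Optimisation settings; epochs is a cap when ``early_stop_loss`` is set."""

    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 200
    n_folds: int = 10
    split_ratio: float = 0.8
    seed: int = 0
    early_stop_loss: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Single-CPU profile: 50-epoch cap with loss-plateau early stopping."""
    kwargs = dict(epochs=50, early_stop_loss=0.1, batch_size=50, seed=seed)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@dataclass
class Metrics:
    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    macro_precision: float
    macro_recall: float
    predictions: np.ndarray | None = None


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    models: list[EFCCNet]
    loss_traces: list[list[float]]

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.fold_metrics])

    def summary(self) -> dict[str, float]:
        acc = self.fold_accuracies
        prec = np.array([m.macro_precision for m in self.fold_metrics])
        rec = np.array([m.macro_recall for m in self.fold_metrics])
        return {
            "accuracy_mean": float(acc.mean()),
            "accuracy_sd": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
            "precision_mean": float(prec.mean()),
            "precision_sd": float(prec.std(ddof=1)) if prec.size > 1 else 0.0,
            "recall_mean": float(rec.mean()),
            "recall_sd": float(rec.std(ddof=1)) if rec.size > 1 else 0.0,
        }


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def stratified_split(
    dataset: EEGDataset,
    ratio: float = 0.8,
    seed: int = 0,
    group_by_subject: bool = False,
) -> tuple[EEGDataset, EEGDataset]:
    """Seeded train/test split preserving per-class proportions.

    ``group_by_subject=True`` instead keeps every subject entirely on one
    side of the split (leakage-free variant; proportions then only
    approximate).
    """
    y = dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    if not group_by_subject and (counts * (1.0 - ratio) < 1.0 - 1e-9).any():
        raise ValueError(
            f"smallest class has {counts.min()} samples; too few for a "
            f"{ratio:.0%} split"
        )
    if group_by_subject:
        splitter = GroupShuffleSplit(n_splits=1, train_size=ratio, random_state=seed)
        train_idx, test_idx = next(splitter.split(y, y, groups=dataset.subjects))
    else:
        splitter = StratifiedShuffleSplit(n_splits=1, train_size=ratio, random_state=seed)
        train_idx, test_idx = next(splitter.split(np.zeros_like(y), y))
    return dataset.select(np.sort(train_idx)), dataset.select(np.sort(test_idx))


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _as_batch(samples: np.ndarray) -> np.ndarray:
    return samples[:, None, :, :]


def train(
    model: EFCCNet,
    samples: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
) -> list[float]:
    """Mini-batch Adam on softmax cross-entropy; returns the per-epoch loss trace."""
    X = _as_batch(np.asarray(samples, dtype=np.float32))
    y = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    model.train_mode()
    trace: list[float] = []
    with T.arena():
        for epoch in range(config.epochs):
            order = rng.permutation(len(y))
            losses = []
            for start in range(0, len(y), config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = model.forward_tensor(X[idx])
                loss = T.cross_entropy_with_logits(logits, y[idx])
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss ({value}) at epoch {epoch}, batch offset "
                        f"{start}; lr={config.learning_rate}, "
                        f"batch_size={config.batch_size}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(value)
                del logits, loss
                T.ARENA.next_step()
            trace.append(float(np.mean(losses)))
            if config.early_stop_loss is not None and trace[-1] < config.early_stop_loss:
                break
    model.eval_mode()
    return trace


def evaluate(
    model: EFCCNet,
    samples: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 100,
    return_predictions: bool = False,
) -> Metrics:
    """Argmax predictions, confusion matrix, and derived metrics."""
    y = np.asarray(labels, dtype=np.int64)
    if y.size == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    X = _as_batch(np.asarray(samples, dtype=np.float32))
    model.eval_mode()
    preds = []
    with T.arena():
        for i in range(0, len(y), batch_size):
            preds.append(model.predict(X[i : i + batch_size]).copy())
            T.ARENA.next_step()
    preds = np.concatenate(preds)
    K = model.config.n_classes
    confusion = np.zeros((K, K), dtype=np.int64)
    np.add.at(confusion, (y, preds), 1)
    metrics = compute_metrics(confusion)
    if return_predictions:
        metrics.predictions = preds
    return metrics


def compute_metrics(confusion: np.ndarray) -> Metrics:
    """One-vs-rest metrics from a confusion matrix (rows true, cols predicted).

    Per class c: TP = M[c,c], FP = sum of column c off the diagonal,
    FN = sum of row c off the diagonal; precision = TP/(TP+FP) and
    recall = TP/(TP+FN), defined as 0 (with a warning) when the denominator
    vanishes.  Accuracy is trace/total; macro scores are unweighted class
    means.
    """
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {M.shape}")
    if (M < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    M = M.astype(np.int64)
    total = M.sum()
    tp = np.diag(M).astype(np.float64)
    fp = M.sum(axis=0) - tp
    fn = M.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    if ((tp + fp) == 0).any() or ((tp + fn) == 0).any():
        warnings.warn("empty precision/recall denominator; reporting 0 for that class")
    accuracy = float(tp.sum() / total) if total else 0.0
    return Metrics(
        confusion=M,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def kfold_cv(
    dataset: EEGDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> CVResult:
    """Stratified k-fold CV; each fold trains a freshly seeded model."""
    y = dataset.labels
    _, counts = np.unique(y, return_counts=True)
    if train_config.n_folds > counts.min():
        raise ValueError(
            f"{train_config.n_folds} folds infeasible: smallest class has "
            f"{counts.min()} samples"
        )
    skf = StratifiedKFold(
        n_splits=train_config.n_folds, shuffle=True, random_state=train_config.seed
    )
    fold_metrics: list[Metrics] = []
    models: list[EFCCNet] = []
    traces: list[list[float]] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        cfg = dataclasses.replace(model_config, seed=model_config.seed + fold)
        fold_train = dataclasses.replace(train_config, seed=train_config.seed + fold)
        model = build_model(cfg)
        traces.append(train(model, dataset.samples[tr_idx], y[tr_idx], fold_train))
        fold_metrics.append(evaluate(model, dataset.samples[va_idx], y[va_idx]))
        models.append(model)
    return CVResult(fold_metrics=fold_metrics, models=models, loss_traces=traces)


def select_best_fold(cv: CVResult) -> EFCCNet:
    """Model of the highest-accuracy fold; ties go to the lowest fold index."""
    if not cv.models:
        raise ValueError("cross-validation produced no folds")
    return cv.models[int(np.argmax(cv.fold_accuracies))]


# ---------------------------------------------------------------------------
# ablation grids
# ---------------------------------------------------------------------------

def _with_specs(base: ModelConfig, name: str, specs: list[BranchSpec]) -> tuple[str, ModelConfig]:
    return name, dataclasses.replace(base, branch_specs=tuple(specs))


def directions_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """Strip-direction ablation: time-only (1xK), space-only (Kx1), both."""
    out = []
    for name, d in [("conv_1xK", "time_only"), ("conv_Kx1", "space_only"), ("conv_both", "both")]:
        specs = [
            dataclasses.replace(s, directions=d) for s in base.resolved_branch_specs()
        ]
        out.append(_with_specs(base, name, specs))
    return out


def branches_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """Branch-subset ablation: the 7 non-empty subsets of the 3 branches."""
    subsets = [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3)]
    out = []
    for subset in subsets:
        specs = [
            dataclasses.replace(s, enabled=s.index in subset)
            for s in base.resolved_branch_specs()
        ]
        out.append(_with_specs(base, "branches_" + "".join(map(str, subset)), specs))
    return out


def components_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """Component ablation: conv / self-attention / residual combinations.

    A residual connection needs a partner stage, leaving six legal cases.
    """
    cases = [
        ("conv", dict(use_conv=True, use_attention=False, use_residual=False)),
        ("attn", dict(use_conv=False, use_attention=True, use_residual=False)),
        ("conv_res", dict(use_conv=True, use_attention=False, use_residual=True)),
        ("attn_res", dict(use_conv=False, use_attention=True, use_residual=True)),
        ("conv_attn", dict(use_conv=True, use_attention=True, use_residual=False)),
        ("conv_attn_res", dict(use_conv=True, use_attention=True, use_residual=True)),
    ]
    out = []
    for name, toggles in cases:
        specs = [dataclasses.replace(s, **toggles) for s in base.resolved_branch_specs()]
        out.append(_with_specs(base, name, specs))
    return out


def channels_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """Structural sweep over deep channel counts with a single EFCM unit."""
    return [
        (f"channels_{c}", dataclasses.replace(base, expansion_channels=c, n_efcm=1))
        for c in (10, 20, 30, 40, 50, 60, 70, 80)
    ]


def efcm_units_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """Structural sweep over the number of stacked EFCM units."""
    return [(f"efcm_units_{n}", dataclasses.replace(base, n_efcm=n)) for n in (1, 2, 3, 4, 5)]


GRIDS = {
    "directions": directions_grid,
    "branches": branches_grid,
    "components": components_grid,
    "channels": channels_grid,
    "efcm_units": efcm_units_grid,
}


def run_ablation(
    grid: list[tuple[str, ModelConfig]],
    dataset: EEGDataset,
    train_config: TrainConfig,
) -> pd.DataFrame:
    """Full cross-validation per grid entry; one mean +/- sd row per entry."""
    rows = []
    for name, config in grid:
        for spec in config.resolved_branch_specs():
            if spec.use_residual and not (spec.use_conv or spec.use_attention):
                raise ValueError(f"illegal configuration {name}: residual without a partner")
        cv = kfold_cv(dataset, config, train_config)
        rows.append({"config_id": name, **cv.summary()})
    return pd.DataFrame(rows)
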