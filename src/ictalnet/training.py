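"""Training: focal loss, AdamW schedule with plateau decay and early stopping,
and the cross-validation driver.

Defaults follow the reference protocol: AdamW at lr 5e-4 / weight decay 1e-3,
focal loss with alpha 0.6 on the abnormal class and gamma 2.0, at most 20
epochs per fold, early stop after 8 epochs without validation-loss
improvement, learning rate x0.3 on a 3-epoch plateau, global gradient-norm
clipping at 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import nn
from .dataset import LabeledDataset, SplitPlan, smote_balance, augment
from .evaluation import FoldResult, confusion, compute_metrics, search_threshold
from .models import Model, ModelSpec, build_model

__all__ = [
    "FocalLossParams",
    "TrainConfig",
    "focal_loss",
    "train_fold",
    "cross_validate",
]

_P_CLAMP = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    """alpha weights the abnormal class (1 - alpha the normal class);
    gamma down-weights easy examples."""

    alpha: float = 0.6
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class TrainConfig:
    lr: float = 5e-4
    weight_decay: float = 1e-3
    epochs: int = 20
    patience: int = 8
    lr_decay_factor: float = 0.3
    lr_plateau_patience: int = 3
    grad_clip_norm: float = 1.0
    batch_size: int = 32
    seed: int = 0
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    monitor: str = "val_loss"  # or "train_loss"

    def __post_init__(self):
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.monitor not in ("val_loss", "train_loss"):
            raise ValueError("monitor must be 'val_loss' or 'train_loss'")


def focal_loss(
    p_abnormal: np.ndarray, y: np.ndarray, params: FocalLossParams | None = None
) -> float:
    """Mean focal loss over a batch of abnormal-class probabilities.

    Per item: P_t = p if y = 1 else 1 - p; weight alpha if y = 1 else
    1 - alpha; loss = -weight * (1 - P_t)^gamma * log(P_t).  Probabilities
    are clamped to [1e-7, 1 - 1e-7] to guard the log.
    """
    params = params or FocalLossParams()
    p = np.clip(np.asarray(p_abnormal, dtype=np.float64), _P_CLAMP, 1.0 - _P_CLAMP)
    y = np.asarray(y)
    p_t = np.where(y == 1, p, 1.0 - p)
    alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    return float(np.mean(-alpha_t * (1.0 - p_t) ** params.gamma * np.log(p_t)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_with_grad(
    logits: np.ndarray, y: np.ndarray, params: FocalLossParams
) -> tuple[float, np.ndarray]:
    """Focal loss on two-class logits and its gradient w.r.t. the logits.

    Chains dL/dP_t through the softmax; mean reduction over the batch.
    """
    n = logits.shape[0]
    p = _softmax(logits.astype(np.float64))
    y = np.asarray(y, dtype=np.int64)
    p_t = np.clip(p[np.arange(n), y], _P_CLAMP, 1.0 - _P_CLAMP)
    alpha_t = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    one_m = 1.0 - p_t
    loss = float(np.mean(-alpha_t * one_m ** params.gamma * np.log(p_t)))
    # dL/dP_t = alpha * [ gamma (1-P)^(g-1) log P - (1-P)^g / P ]
    g = params.gamma
    dl_dpt = alpha_t * (
        (g * one_m ** (g - 1.0) * np.log(p_t) if g > 0 else 0.0) - one_m ** g / p_t
    )
    # dP_t/dz_j = P_t (delta_{j=y} - p_j)
    grad = p * (-p_t[:, None])
    grad[np.arange(n), y] += p_t
    grad *= dl_dpt[:, None] / n
    return loss, grad.astype(np.float32)


def _epoch_minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo : lo + batch_size]


def train_fold(
    model: Model,
    train_items: tuple[np.ndarray, np.ndarray],
    val_items: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[Model, dict]:
    """Optimize ``model`` on (X, y) train data, monitoring a validation set.

    Returns the model restored to its best-monitored weights and a history
    dict with per-epoch train/validation losses, accuracy, and learning rate.
    Two calls with identical seed, data, and initial weights are bit-identical.
    """
    x_train, y_train = train_items
    x_val, y_val = val_items
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation subsets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model.set_rng(rng)
    opt = nn.AdamW(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best = np.inf
    best_state = model.state_dict()
    since_improve = 0
    since_plateau = 0
    for epoch in range(1, cfg.epochs + 1):
        model.train(True)
        losses = []
        for idx in _epoch_minibatches(len(x_train), cfg.batch_size, rng):
            xb = np.asarray(x_train[idx], dtype=np.float32)
            yb = y_train[idx]
            opt.zero_grad()
            logits = model.forward(xb)
            loss, dlogits = focal_loss_with_grad(logits, yb, cfg.focal)
            model.backward(dlogits)
            nn.clip_grad_norm(model.params(), cfg.grad_clip_norm)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        proba = model.predict_proba(x_val, batch_size=cfg.batch_size)
        val_loss = focal_loss(proba[:, 1], y_val, cfg.focal)
        val_acc = float(((proba[:, 1] >= 0.5).astype(int) == y_val).mean())
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        monitored = val_loss if cfg.monitor == "val_loss" else train_loss
        if monitored < best - 1e-12:
            best = monitored
            best_state = model.state_dict()
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
            if since_plateau >= cfg.lr_plateau_patience:
                opt.lr *= cfg.lr_decay_factor
                since_plateau = 0
            if since_improve >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


def _class_conditional_augment(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Noise/scaling on abnormal maps, time shifting on normal maps."""
    rng = np.random.default_rng(seed)
    maps = []
    for i, m in enumerate(ds.maps):
        item_seed = int(rng.integers(0, 2**31 - 1))
        if ds.labels[i] == 1:
            maps.append(augment(m, 1, ops=("noise", "scale"), seed=item_seed))
        else:
            maps.append(augment(m, 0, ops=("shift",), seed=item_seed))
    return LabeledDataset(maps, ds.labels.copy(), list(ds.subject_ids),
                          list(ds.provenance))


def _split_validation(n, frac, rng):
    order = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return order[n_val:], order[:n_val]


def cross_validate(
    ds: LabeledDataset,
    spec: ModelSpec,
    cfg: TrainConfig,
    plan: SplitPlan,
    balance: bool = True,
    do_augment: bool = True,
    balance_before_split: bool = False,
    val_frac: float = 0.1,
    threshold_objective: str = "f1",
) -> list[FoldResult]:
    """Train and evaluate one model per fold of ``plan``.

    Default order: split first, then SMOTE-balance and augment the train
    side only, so no resampled or augmented item can reach a test fold.
    ``balance_before_split=True`` instead balances the full dataset before
    splitting (the reference protocol's order, at the cost of possible
    leakage through interpolated samples).  The decision threshold is chosen
    on the train fold's held-out validation split and frozen before the test
    fold is scored.
    """
    if balance_before_split and balance:
        ds = smote_balance(ds, seed=cfg.seed)
    if plan.mode == "kfold":
        if plan.fold_of_item.shape[0] != len(ds):
            raise ValueError(
                f"plan covers {plan.fold_of_item.shape[0]} items, dataset has {len(ds)}"
            )
        fold_ids = range(plan.n_splits)
        splits = [(plan.train_indices(f), plan.test_indices(f)) for f in fold_ids]
    else:
        subj = np.asarray(ds.subject_ids)
        train_idx = np.where(np.isin(subj, sorted(plan.train_subjects)))[0]
        test_idx = np.where(np.isin(subj, sorted(plan.test_subjects)))[0]
        if train_idx.size + test_idx.size != len(ds):
            raise ValueError("subject plan does not cover the dataset")
        splits = [(train_idx, test_idx)]
    results = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        rng = np.random.default_rng(cfg.seed + 1000 * fold)
        train_ds = ds.subset(train_idx)
        test_ds = ds.subset(test_idx)
        if not balance_before_split:
            assert all(p != "smote" for p in test_ds.provenance), (
                "leakage: resampled item in a test fold"
            )
        tr, va = _split_validation(len(train_ds), val_frac, rng)
        val_ds = train_ds.subset(va)
        fit_ds = train_ds.subset(tr)
        if balance and not balance_before_split:
            # k adapts to small folds; balancing is skipped when the minority
            # class is too small to interpolate at all
            n_min = int(min((fit_ds.labels == 1).sum(), (fit_ds.labels == 0).sum()))
            if n_min >= 2:
                fit_ds = smote_balance(
                    fit_ds, seed=cfg.seed + fold, k=min(5, n_min - 1)
                )
        if do_augment:
            fit_ds = _class_conditional_augment(fit_ds, seed=cfg.seed + fold)
        model = build_model(spec, seed=cfg.seed + fold)
        fold_cfg = dc_replace(cfg, seed=cfg.seed + fold)
        model, history = train_fold(
            model,
            (fit_ds.stacked(), fit_ds.labels),
            (val_ds.stacked(), val_ds.labels),
            fold_cfg,
        )
        val_proba = model.predict_proba(val_ds.stacked(), cfg.batch_size)[:, 1]
        threshold, _ = search_threshold(
            val_ds.labels, val_proba, objective=threshold_objective
        )
        test_proba = model.predict_proba(test_ds.stacked(), cfg.batch_size)[:, 1]
        counts = confusion(test_ds.labels, test_proba, threshold)
        metrics = compute_metrics(counts, threshold=threshold)
        results.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=metrics,
                threshold=threshold,
                history=history,
                test_indices=np.asarray(test_idx),
                test_proba=test_proba,
            )
        )
    return results
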