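"""Labeled time-frequency datasets: class balancing, augmentation, splits.

Class balance follows the 2:1 normal:abnormal convention, reached by SMOTE
oversampling of the deficient class (convex interpolation between a sample
and one of its k nearest same-class neighbours in flattened-map space).
Augmentation is class-conditional by default: Gaussian noise / amplitude
scaling on abnormal maps, time shifting (+/-10%) on normal maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

from .timefreq import TFMap

__all__ = [
    "LabeledDataset",
    "SplitPlan",
    "smote_balance",
    "augment",
    "kfold_plan",
    "subject_split",
]

AUG_OPS = ("noise", "shift", "scale")


@dataclass
class LabeledDataset:
    """TFMaps with binary labels (0 normal / 1 abnormal) and subject provenance."""

    maps: list[TFMap]
    labels: np.ndarray
    subject_ids: list[str]
    provenance: list[str] = field(default_factory=list)  # real | synthetic | smote

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.maps) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("maps, labels and subject_ids must have equal length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if not self.provenance:
            self.provenance = ["synthetic"] * len(self.maps)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def n_normal(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def n_abnormal(self) -> int:
        return int((self.labels == 1).sum())

    def stacked(self, dtype=np.float32) -> np.ndarray:
        """All map values as one (n_items, n_channels, n_freq, n_time) array."""
        return np.stack([m.values for m in self.maps]).astype(dtype, copy=False)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            maps=[self.maps[i] for i in idx],
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
        )


@dataclass
class SplitPlan:
    """Either a k-fold item assignment or a subject partition."""

    fold_of_item: np.ndarray | None = None  # item -> fold index
    train_subjects: frozenset | None = None
    test_subjects: frozenset | None = None
    n_splits: int = 0
    seed: int = 0

    @property
    def mode(self) -> str:
        return "kfold" if self.fold_of_item is not None else "subject_independent"

    def test_indices(self, fold: int) -> np.ndarray:
        if self.fold_of_item is None:
            raise ValueError("not a k-fold plan")
        return np.where(self.fold_of_item == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        if self.fold_of_item is None:
            raise ValueError("not a k-fold plan")
        return np.where(self.fold_of_item != fold)[0]

    def to_json(self) -> str:
        if self.fold_of_item is not None:
            payload = {
                "mode": "kfold",
                "n_splits": self.n_splits,
                "seed": self.seed,
                "folds": {
                    str(f): self.test_indices(f).tolist() for f in range(self.n_splits)
                },
            }
        else:
            payload = {
                "mode": "subject_independent",
                "seed": self.seed,
                "train_subjects": sorted(self.train_subjects),
                "test_subjects": sorted(self.test_subjects),
            }
        return json.dumps(payload, indent=1)


def _flatten(maps: list[TFMap]) -> np.ndarray:
    return np.stack([m.values.reshape(-1) for m in maps]).astype(np.float32, copy=False)


def smote_balance(
    ds: LabeledDataset, target_ratio: float = 2.0, k: int = 5, seed: int = 0
) -> LabeledDataset:
    """Oversample the deficient class until n_normal / n_abnormal = target_ratio.

    Synthetic items are convex combinations x = p1 + lam*(p2 - p1), lam ~
    U(0,1), of a class member and one of its k nearest same-class neighbours
    in flattened-map space; they carry provenance "smote".  A dataset already
    at the target ratio is returned unchanged.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    n_norm, n_abn = ds.n_normal, ds.n_abnormal
    if n_norm == round(target_ratio * n_abn):
        return ds
    if n_norm > target_ratio * n_abn:
        minority_label, n_target = 1, int(round(n_norm / target_ratio))
    else:
        minority_label, n_target = 0, int(round(target_ratio * n_abn))
    minority_idx = np.where(ds.labels == minority_label)[0]
    n_new = n_target - minority_idx.size
    if n_new <= 0:
        return ds
    if minority_idx.size < k + 1:
        raise ValueError(
            f"class {minority_label} has {minority_idx.size} items; SMOTE with k={k} "
            f"needs at least {k + 1}"
        )
    rng = np.random.default_rng(seed)
    flat = _flatten([ds.maps[i] for i in minority_idx])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(flat)
    _, neigh = nn.kneighbors(flat)  # column 0 is the point itself
    new_maps, new_subj = [], []
    picks = rng.integers(0, minority_idx.size, size=n_new)
    for j in picks:
        partner = int(neigh[j, rng.integers(1, k + 1)])
        lam = rng.uniform()
        parent = ds.maps[minority_idx[j]]
        other = ds.maps[minority_idx[partner]]
        values = parent.values + lam * (other.values - parent.values)
        new_maps.append(replace(parent, values=values))
        new_subj.append(ds.subject_ids[minority_idx[j]])
    return LabeledDataset(
        maps=ds.maps + new_maps,
        labels=np.concatenate([ds.labels, np.full(n_new, minority_label, dtype=np.int64)]),
        subject_ids=ds.subject_ids + new_subj,
        provenance=ds.provenance + ["smote"] * n_new,
    )


def augment(
    tfmap: TFMap,
    label: int,
    ops: tuple[str, ...] = AUG_OPS,
    seed: int = 0,
    noise_sigma_rel: float = 0.05,
    shift_frac: float = 0.10,
    scale_range: tuple[float, float] = (0.8, 1.2),
) -> TFMap:
    """Augment one map; the label is unchanged by construction.

    noise: add N(0, (sigma_rel * map SD)^2); shift: displace the time axis by
    a uniform draw in [-shift_frac, +shift_frac] of n_time with zero fill;
    scale: multiply by a uniform draw from ``scale_range``.
    """
    unknown = set(ops) - set(AUG_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation op(s) {sorted(unknown)}; valid: {AUG_OPS}")
    rng = np.random.default_rng(seed)
    values = tfmap.values.copy()
    n_time = values.shape[-1]
    if "shift" in ops and shift_frac > 0:
        shift = int(rng.uniform(-shift_frac, shift_frac) * n_time)
        if shift:
            values = np.roll(values, shift, axis=-1)
            if shift > 0:
                values[..., :shift] = 0
            else:
                values[..., shift:] = 0
    if "noise" in ops and noise_sigma_rel > 0:
        sd = float(tfmap.values.std())
        values = values + rng.normal(0, noise_sigma_rel * sd, size=values.shape).astype(
            values.dtype
        )
    if "scale" in ops and scale_range != (1.0, 1.0):
        values = values * rng.uniform(*scale_range)
    return replace(tfmap, values=values)


def kfold_plan(n_items: int, n_splits: int = 5, shuffle: bool = True, seed: int = 42) -> SplitPlan:
    """Mutually exclusive, jointly exhaustive folds of near-equal size."""
    if n_items < n_splits:
        raise ValueError(f"cannot split {n_items} items into {n_splits} folds")
    kf = KFold(n_splits=n_splits, shuffle=shuffle, random_state=seed if shuffle else None)
    fold_of_item = np.empty(n_items, dtype=np.int64)
    for f, (_, test_idx) in enumerate(kf.split(np.arange(n_items))):
        fold_of_item[test_idx] = f
    return SplitPlan(fold_of_item=fold_of_item, n_splits=n_splits, seed=seed)


def subject_split(ds: LabeledDataset, n_train_subjects: int = 16, seed: int = 0) -> SplitPlan:
    """Partition by subject: no subject appears on both sides."""
    subjects = sorted(set(ds.subject_ids))
    if len(subjects) < n_train_subjects + 1:
        raise ValueError(
            f"need at least {n_train_subjects + 1} distinct subjects, have {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    train = rng.choice(len(subjects), size=n_train_subjects, replace=False)
    train_subjects = frozenset(subjects[i] for i in train)
    test_subjects = frozenset(subjects) - train_subjects
    return SplitPlan(
        train_subjects=train_subjects, test_subjects=test_subjects, seed=seed
    )
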