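"""Wrapper feature selection: KNN hold-out fitness driven by RBMO/IRBMO.

A candidate feature subset is scored by a K-nearest-neighbour classifier
on a stratified 75/25 train/test split of the dataset:

    fitness = alpha * (1 - test accuracy) + (1 - alpha) * |subset| / D

with ``alpha = 0.99`` by default, so classification error dominates and
subset size breaks near-ties toward parsimony.  Lower is better.  The
optimizer searches ``[0, 1]^D``; positions are binarized by one of the
rules in :mod:`magpiefs.binarization` before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .binarization import TransferSpec, apply_transfer, threshold_binarize
from .data_io import LabeledDataset
from .metrics import multiclass_metrics
from .optimizers import OptimizerConfig, RunTrace, run_optimizer

__all__ = [
    "FitnessConfig",
    "FSResult",
    "split_dataset",
    "knn_predict",
    "evaluate_mask",
    "select_features",
]


@dataclass
class FitnessConfig:
    """Weights and classifier settings for the wrapper fitness."""

    alpha: float = 0.99
    k_neighbors: int = 5
    train_fraction: float = 0.75
    empty_mask_policy: str = "penalty"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.empty_mask_policy not in ("penalty", "repair"):
            raise ValueError("empty_mask_policy must be 'penalty' or 'repair'")


@dataclass
class FSResult:
    """Outcome of one feature-selection run."""

    mask: np.ndarray
    fitness: float
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    n_selected: int
    curve: np.ndarray
    trace: RunTrace = field(repr=False)


def split_dataset(
    data: LabeledDataset,
    train_fraction: float = 0.75,
    rng: np.random.Generator | int | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split; per-class train counts track
    ``train_fraction`` within one sample."""
    counts = np.bincount(data.labels)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    idx_train, idx_test = train_test_split(
        np.arange(data.n_samples),
        train_size=train_fraction,
        stratify=data.labels,
        random_state=seed,
    )
    def subset(idx):
        return LabeledDataset(
            features=data.features[idx],
            labels=data.labels[idx],
            feature_names=list(data.feature_names),
            class_labels=list(data.class_labels),
        )
    return subset(idx_train), subset(idx_test)


def _minmax_fit(train_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = train_features.min(axis=0)
    span = train_features.max(axis=0) - lo
    span[span == 0.0] = 1.0  # constant columns map to 0
    return lo, span


def knn_predict(
    train: LabeledDataset,
    test: LabeledDataset,
    mask: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Majority-vote KNN over the selected features.

    Features are min-max scaled with train-set ranges only.  Distance ties
    resolve toward the lower training-row index (stable sort); vote ties
    resolve toward the tied class with the smallest aggregate neighbour
    distance, then the smallest class index.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    lo, span = _minmax_fit(train.features[:, mask])
    xtr = (train.features[:, mask] - lo) / span
    xte = (test.features[:, mask] - lo) / span
    k = min(k, xtr.shape[0])
    dist = cdist(xte, xtr)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neigh_labels = train.labels[order]  # (n_test, k)
    neigh_dist = np.take_along_axis(dist, order, axis=1)

    n_classes = int(train.labels.max()) + 1
    onehot = np.eye(n_classes, dtype=float)[neigh_labels]  # (n_test, k, C)
    votes = onehot.sum(axis=1)
    agg = (onehot * neigh_dist[:, :, None]).sum(axis=1)
    # lexicographic (votes desc, aggregate distance asc, class index asc):
    # votes are integers and agg < k * sqrt(D) after scaling, so a scaled
    # penalty keeps the ordering exact.
    big = float(agg.max()) + 1.0
    score = votes * big - agg
    return np.argmax(score, axis=1)


def evaluate_mask(
    mask: np.ndarray,
    train: LabeledDataset,
    test: LabeledDataset,
    config: FitnessConfig = FitnessConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """Wrapper fitness of a bit mask (lower is better).

    An empty mask is scored 1.0 under the ``penalty`` policy; under
    ``repair`` one uniformly chosen bit is set before evaluation (the
    caller's ``mask`` is not modified).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        if config.empty_mask_policy == "penalty":
            return 1.0
        mask = mask.copy()
        rng = rng if rng is not None else np.random.default_rng()
        mask[rng.integers(mask.size)] = True
    pred = knn_predict(train, test, mask, config.k_neighbors)
    error = float(np.mean(pred != test.labels))
    size_ratio = mask.sum() / mask.size
    return config.alpha * error + (1.0 - config.alpha) * size_ratio


class _MaskObjective:
    """Continuous objective over [0,1]^D wrapping binarization + KNN fitness.

    For V-family transfers each agent keeps a persistent bit mask that the
    flip rule mutates; threshold/S transfers re-binarize from the
    continuous position every evaluation.
    """

    def __init__(self, train, test, fitness_config, transfer, rng):
        self.train = train
        self.test = test
        self.config = fitness_config
        self.transfer = transfer
        self.rng = rng
        self.masks: dict[int, np.ndarray] = {}
        self.best_mask: np.ndarray | None = None
        self.best_fitness = np.inf

    def __call__(self, x: np.ndarray, agent: int) -> float:
        if self.transfer.family == "V":
            current = self.masks.get(agent)
            if current is None:
                current = threshold_binarize(x)
            mask = apply_transfer(x, current, self.transfer, self.rng)
            self.masks[agent] = mask
        else:
            mask = apply_transfer(x, None, self.transfer, self.rng)
        fit = evaluate_mask(mask, self.train, self.test, self.config, self.rng)
        if fit < self.best_fitness and mask.sum() > 0:
            self.best_fitness = fit
            self.best_mask = mask.copy()
        return fit


def select_features(
    data: LabeledDataset,
    optimizer_config: OptimizerConfig | None = None,
    fitness_config: FitnessConfig = FitnessConfig(),
    transfer: TransferSpec | str = "threshold",
    variant: str = "irbmo",
    seed: int | None = None,
) -> FSResult:
    """Run one wrapper feature-selection optimization on ``data``.

    The stratified split, the swarm trajectory, and any stochastic
    binarization all derive from a single seed (``seed`` or
    ``optimizer_config.seed``), so results are fully reproducible.
    """
    if isinstance(transfer, str):
        transfer = TransferSpec.from_name(transfer)
    if optimizer_config is None:
        optimizer_config = OptimizerConfig(dim=data.n_features, seed=seed or 0)
    if optimizer_config.dim != data.n_features:
        raise ValueError(
            f"optimizer dim {optimizer_config.dim} != n_features {data.n_features}"
        )
    if seed is not None:
        optimizer_config.seed = seed
    root = np.random.default_rng(optimizer_config.seed)
    train, test = split_dataset(data, fitness_config.train_fraction, root)
    objective = _MaskObjective(
        train, test, fitness_config, transfer, np.random.default_rng(root.integers(2**31))
    )
    trace = run_optimizer(objective, optimizer_config, variant)

    best_mask = objective.best_mask
    if best_mask is None:  # every evaluated mask was empty (pathological)
        best_mask = np.ones(data.n_features, dtype=np.int8)
    pred = knn_predict(train, test, best_mask, fitness_config.k_neighbors)
    rec = multiclass_metrics(test.labels, pred)
    return FSResult(
        mask=np.asarray(best_mask, dtype=np.int8),
        fitness=objective.best_fitness if np.isfinite(objective.best_fitness) else trace.best_fitness,
        accuracy=rec["accuracy"],
        sensitivity=rec["sensitivity"],
        specificity=rec["specificity"],
        f_score=rec["f_score"],
        n_selected=int(np.sum(best_mask)),
        curve=trace.curve,
        trace=trace,
    )
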