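"""Dataset loading (CSV/ARFF) and synthetic classification data.

The loader targets UCI/KEEL-style tabular files: numeric feature columns
plus one categorical label column.  The synthetic generator plants a known
feature structure — informative columns whose class-conditional means are
separated, redundant columns that are linear combinations of informative
ones, and pure-noise columns — so that recovery of the informative set is
a testable ground truth.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = ["LabeledDataset", "SyntheticSpec", "load_dataset", "save_dataset", "generate_synthetic"]


@dataclass
class LabeledDataset:
    """A classification problem: numeric features plus integer-coded labels.

    ``labels`` are contiguous integers ``0..n_classes-1`` in order of first
    appearance; ``class_labels`` maps them back to the original values.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    class_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.features.shape[1] < 2:
            raise ValueError("need at least 2 features")
        if not self.class_labels:
            self.class_labels = list(np.unique(self.labels))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


@dataclass
class SyntheticSpec:
    """Recipe for a planted-structure classification dataset.

    ``class_sep`` is the distance between class-conditional means of each
    informative feature in units of its (unit) standard deviation;
    ``label_noise`` is the probability a label is flipped after assignment.
    """

    n_samples: int = 300
    n_informative: int = 5
    n_redundant: int = 0
    n_noise: int = 15
    class_sep: float = 2.0
    label_noise: float = 0.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _encode_labels(raw: pd.Series) -> tuple[np.ndarray, list]:
    """Map labels to 0..K-1 in order of first appearance."""
    seen: dict = {}
    codes = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        if v not in seen:
            seen[v] = len(seen)
        codes[i] = seen[v]
    return codes, list(seen)


def load_dataset(
    path: str | Path,
    label_column: str | int = -1,
    delimiter: str | None = None,
) -> LabeledDataset:
    """Load a delimited text or ARFF classification table.

    Rows with missing labels are dropped; missing numeric feature values
    are imputed with the column median.  ``label_column`` may be a column
    name or a positional index (negative indices count from the end).
    """
    path = Path(path)
    if path.suffix.lower() == ".arff":
        data, meta = scipy_arff.loadarff(io.StringIO(path.read_text()))
        df = pd.DataFrame(data)
        for col in df.columns:  # scipy returns nominal attributes as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        if delimiter is None:
            delimiter = _sniff_delimiter(path.read_text()[:4096])
        df = pd.read_csv(path, sep=delimiter)

    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
        label_name = label_column

    df = df.dropna(subset=[label_name])
    labels_raw = df[label_name]
    feat = df.drop(columns=[label_name])
    for col in feat.columns:
        try:
            feat[col] = pd.to_numeric(feat[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"feature column {col!r} is not numeric and cannot be coerced") from exc
        if feat[col].isna().any():
            feat[col] = feat[col].fillna(feat[col].median())
    codes, class_labels = _encode_labels(labels_raw)
    return LabeledDataset(
        features=feat.to_numpy(dtype=float),
        labels=codes,
        feature_names=[str(c) for c in feat.columns],
        class_labels=class_labels,
    )


def save_dataset(data: LabeledDataset, path: str | Path, label_column: str = "label") -> None:
    """Write a dataset as CSV (features then label column)."""
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = [data.class_labels[c] for c in data.labels]
    df.to_csv(path, index=False)


def generate_synthetic(spec: SyntheticSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Generate a dataset with planted informative/redundant/noise columns.

    Returns the dataset and a boolean mask over columns marking the
    ``n_informative`` informative ones.  Informative features are
    class-conditional Gaussians with unit variance and means ``class_sep``
    apart per class; redundant features are random linear combinations of
    the informative block plus small (sd 0.05) Gaussian noise; noise
    features are standard normal, independent of the labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.arange(n) % spec.n_classes  # balanced
    rng.shuffle(labels)

    informative = rng.normal(size=(n, spec.n_informative))
    informative += spec.class_sep * labels[:, None]

    blocks = [informative]
    if spec.n_redundant:
        weights = rng.normal(size=(spec.n_informative, spec.n_redundant))
        weights /= np.linalg.norm(weights, axis=0, keepdims=True)
        blocks.append(informative @ weights + rng.normal(scale=0.05, size=(n, spec.n_redundant)))
    if spec.n_noise:
        blocks.append(rng.normal(size=(n, spec.n_noise)))
    features = np.hstack(blocks)

    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        shift = rng.integers(1, spec.n_classes, size=n)
        labels = np.where(flip, (labels + shift) % spec.n_classes, labels)

    names = (
        [f"inf_{j}" for j in range(spec.n_informative)]
        + [f"red_{j}" for j in range(spec.n_redundant)]
        + [f"noise_{j}" for j in range(spec.n_noise)]
    )
    truth = np.zeros(spec.n_features, dtype=bool)
    truth[: spec.n_informative] = True
    dataset = LabeledDataset(
        features=features,
        labels=labels.astype(int),
        feature_names=names,
        class_labels=list(range(spec.n_classes)),
    )
    return dataset, truth
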