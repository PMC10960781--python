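"""Labeled batches of feature vectors with probabilistic (soft) labels.

A :class:`LabeledBatch` is the unit every augmentation operator consumes and
emits: an ``m x D`` real feature matrix together with an ``m x K``
row-stochastic label matrix.  Integer class labels are converted to one-hot
rows on construction; probability rows supplied by the caller are validated
but never re-normalized, so silent caller bugs surface as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledBatch", "one_hot_encode", "LabelValidityError"]

#: tolerance for "each label row sums to one"
LABEL_SUM_ATOL = 1e-9


class LabelValidityError(ValueError):
    """Raised when a label matrix is not row-stochastic."""


def one_hot_encode(class_indices: np.ndarray, class_count: int) -> np.ndarray:
    """Convert integer class indices to one-hot probability rows.

    Parameters
    ----------
    class_indices
        Integer vector of length ``m`` with entries in ``[0, class_count)``.
    class_count
        Number of classes ``K``.

    Returns
    -------
    ``(m, K)`` float matrix with a single 1 per row.
    """
    idx = np.asarray(class_indices)
    if idx.ndim != 1:
        raise ValueError(f"class indices must be a 1-D vector, got shape {idx.shape}")
    if not np.issubdtype(idx.dtype, np.integer):
        if not np.all(idx == np.floor(idx)):
            raise ValueError("class indices must be integers")
        idx = idx.astype(np.int64)
    if class_count < 1:
        raise ValueError(f"class_count must be >= 1, got {class_count}")
    if idx.size and (idx.min() < 0 or idx.max() >= class_count):
        raise ValueError(
            f"class index out of range [0, {class_count}): "
            f"min={idx.min()}, max={idx.max()}"
        )
    out = np.zeros((idx.size, class_count), dtype=np.float64)
    out[np.arange(idx.size), idx] = 1.0
    return out


def _validate_labels(labels: np.ndarray) -> None:
    if np.any(labels < 0):
        raise LabelValidityError("label matrix has negative entries")
    sums = labels.sum(axis=1)
    bad = np.abs(sums - 1.0) > LABEL_SUM_ATOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise LabelValidityError(
            f"label row {i} sums to {sums[i]!r}, expected 1 within {LABEL_SUM_ATOL}"
        )


@dataclass
class LabeledBatch:
    """Feature matrix plus row-stochastic soft labels.

    ``labels`` may be given either as an ``(m, K)`` probability matrix or as
    an integer vector of class indices (then ``class_count`` is required to
    fix ``K``; otherwise it is inferred as ``max+1``).
    """

    features: np.ndarray
    labels: np.ndarray
    class_count: int = field(default=0)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {self.features.shape}")
        labels = np.asarray(self.labels)
        if labels.ndim == 1:
            k = self.class_count or int(labels.max()) + 1
            labels = one_hot_encode(labels, k)
        labels = np.asarray(labels, dtype=np.float64)
        if labels.ndim != 2:
            raise ValueError(f"labels must be 1-D indices or a 2-D matrix")
        if labels.shape[0] != self.features.shape[0]:
            raise ValueError(
                f"feature rows ({self.features.shape[0]}) != label rows ({labels.shape[0]})"
            )
        if self.features.shape[0] < 2:
            raise ValueError("a batch needs at least 2 samples")
        _validate_labels(labels)
        if self.class_count and self.class_count != labels.shape[1]:
            raise ValueError(
                f"class_count={self.class_count} but label matrix has {labels.shape[1]} columns"
            )
        self.labels = labels
        self.class_count = labels.shape[1]

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def ambient_dim(self) -> int:
        return self.features.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Argmax class index per row."""
        return np.argmax(self.labels, axis=1)

    # -- I/O -------------------------------------------------------------
    def to_npz(self, path: str | Path) -> None:
        np.savez(path, features=self.features, labels=self.labels)

    @classmethod
    def from_npz(cls, path: str | Path) -> "LabeledBatch":
        with np.load(path) as data:
            return cls(features=data["features"], labels=data["labels"])

    def to_csv(self, path: str | Path) -> None:
        """Write a delimited table: feature columns ``x0..`` then label
        columns ``class_0..class_{K-1}``."""
        cols = {f"x{j}": self.features[:, j] for j in range(self.ambient_dim)}
        cols.update(
            {f"class_{k}": self.labels[:, k] for k in range(self.class_count)}
        )
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledBatch":
        df = pd.read_csv(path)
        label_cols = sorted(
            (c for c in df.columns if c.startswith("class_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if not label_cols:
            raise ValueError("CSV has no 'class_*' label columns")
        feat_cols = [c for c in df.columns if c not in label_cols]
        return cls(
            features=df[feat_cols].to_numpy(dtype=np.float64),
            labels=df[label_cols].to_numpy(dtype=np.float64),
        )
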