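"""Labeled feature tables: the common in-memory container and TSV/CSV I/O.

A :class:`LabeledDataset` is a plain (features, labels) pair with an explicit,
ordered list of class names.  The class-name order is significant throughout
the package: it fixes the row order of every coding matrix built for the
dataset, so it is stored alongside the data and serialized with trained
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """N instances with d numeric features and one class label each.

    Parameters
    ----------
    features : ndarray of shape (N, d)
    labels : list of str, length N
    class_names : ordered list of the K distinct class identifiers.  Defaults
        to the sorted unique labels.  Every label must occur in it.
    """

    features: np.ndarray
    labels: list[str]
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one instance and one feature")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} feature rows")
        if self.class_names is None:
            self.class_names = sorted(set(self.labels))
        else:
            self.class_names = [str(c) for c in self.class_names]
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names contains duplicates")
        missing = set(self.labels) - set(self.class_names)
        if missing:
            raise ValueError(f"labels not listed in class_names: {sorted(missing)}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_indices(self) -> np.ndarray:
        """Labels as integer indices into ``class_names``."""
        lookup = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lookup[l] for l in self.labels], dtype=int)

    def subset(self, idx) -> "LabeledDataset":
        """Row subset; preserves the full class_names order."""
        idx = np.asarray(idx)
        return LabeledDataset(
            self.features[idx],
            [self.labels[i] for i in np.atleast_1d(idx)],
            class_names=list(self.class_names),
        )

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_delimited(cls, path, sep: str = "\t",
                       class_names: list[str] | None = None) -> "LabeledDataset":
        """Read a delimited table: feature columns then a final label column.

        A header row is required; any column names are accepted.
        """
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] < 2:
            raise ValueError("need at least one feature column and a label column")
        feats = df.iloc[:, :-1].to_numpy(dtype=float)
        labels = df.iloc[:, -1].astype(str).tolist()
        return cls(feats, labels, class_names=class_names)

    def to_delimited(self, path, sep: str = "\t") -> None:
        cols = [f"f{j}" for j in range(self.dim)]
        df = pd.DataFrame(self.features, columns=cols)
        df["label"] = self.labels
        df.to_csv(path, sep=sep, index=False)
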