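"""Labeled numeric data matrices and their delimited-text readers/writers.

A :class:`Dataset` is the point estimate the whole pipeline operates on: an
``N x D`` real matrix (samples x features) with unique sample and feature
names.  Files are plain CSV/TSV with a header row of feature names and a
first column of sample names, the format produced by most expression-matrix
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_dataset", "write_dataset"]


@dataclass
class Dataset:
    """An ``N x D`` matrix of sample measurements with row/column labels.

    Parameters
    ----------
    values : ndarray of shape (N, D)
        Finite real measurements, arbitrary units.
    sample_names : sequence of str, length N
        Unique row labels.
    feature_names : sequence of str, length D
        Unique column labels.
    """

    values: np.ndarray
    sample_names: list[str] = field(default=None)
    feature_names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.sample_names is None:
            self.sample_names = [f"sample{i}" for i in range(n)]
        if self.feature_names is None:
            self.feature_names = [f"feature{j}" for j in range(d)]
        self.sample_names = [str(s) for s in self.sample_names]
        self.feature_names = [str(s) for s in self.feature_names]
        if len(self.sample_names) != n:
            raise ValueError("sample_names length does not match values")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match values")
        if len(set(self.sample_names)) != n:
            raise ValueError("sample names must be unique")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_names, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Dataset":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_names=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(path: str | Path) -> Dataset:
    """Read a Dataset from CSV/TSV (header = features, first column = samples)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return Dataset.from_frame(frame)


def write_dataset(data: Dataset, path: str | Path) -> None:
    path = Path(path)
    data.to_frame().to_csv(path, sep=_sep_for(path))
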