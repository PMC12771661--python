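"""Labeled symmetric dissimilarity matrices.

The same container carries species-by-species distances (feeding Rao's
quadratic entropy) and plot-by-plot beta-diversity values (feeding the
group-dispersion stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DissimilarityMatrix"]

_SYMMETRY_TOL = 1e-12


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal, non-negative distance matrix with labels.

    Parameters
    ----------
    labels
        Ordered entity names (species or plot identifiers), unique.
    values
        Square array of distances; symmetrised on input if the asymmetry
        is within floating-point noise, rejected otherwise.
    """

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in dissimilarity matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if n and np.nanmax(np.abs(self.values - self.values.T), initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric within 1e-12")
        if np.any(self.values < 0):
            raise ValueError("negative entries in dissimilarity matrix")
        if n and np.max(np.abs(np.diagonal(self.values))) > _SYMMETRY_TOL:
            raise ValueError("nonzero diagonal in dissimilarity matrix")
        # exact symmetry/zero-diagonal after validation
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def reorder(self, labels: list[str]) -> "DissimilarityMatrix":
        """Return a copy with rows/columns permuted to ``labels``."""
        idx = [self.index_of(l) for l in labels]
        return DissimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def subset(self, labels: list[str]) -> "DissimilarityMatrix":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels absent from matrix: {missing}")
        return self.reorder(list(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        if list(df.index) != list(df.columns):
            df = df.loc[:, df.index]
        return cls([str(x) for x in df.index], df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_frame(df)
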