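"""Multivariate homogeneity of group dispersions.

A plot-pairwise dissimilarity matrix is embedded by principal coordinates
analysis (Gower double-centering of -D^2/2). Non-Euclidean dissimilarities
produce negative eigenvalues; their axes form an "imaginary" block whose
squared contributions are subtracted, so that

    d_ij^2 = sum_pos (x_i - x_j)^2 - sum_neg (x_i - x_j)^2

reconstructs the input exactly. Each plot's distance to its group's center
(centroid or spatial median) in this signed geometry is the per-plot beta
diversity response used downstream: larger distance, more distinct
composition relative to the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import DissimilarityMatrix

__all__ = ["PCoAEmbedding", "DispersionResult", "pcoa_decompose", "distance_to_center"]

logger = logging.getLogger(__name__)

_EIG_REL_TOL = 1e-10


@dataclass
class PCoAEmbedding:
    """Principal-coordinate axes split by eigenvalue sign."""

    plot_ids: list[str]
    positive_axes: np.ndarray = field(repr=False)  # n_plots x k_pos
    negative_axes: np.ndarray = field(repr=False)  # n_plots x k_neg
    eigenvalues: np.ndarray = field(repr=False)  # descending, both signs

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def squared_distances(self) -> np.ndarray:
        """Signed squared inter-plot distances (pos block minus neg block)."""

        def sq(a: np.ndarray) -> np.ndarray:
            if a.shape[1] == 0:
                return np.zeros((a.shape[0], a.shape[0]))
            g = a @ a.T
            s = np.diagonal(g)
            return s[:, None] + s[None, :] - 2 * g

        return sq(self.positive_axes) - sq(self.negative_axes)


@dataclass
class DispersionResult:
    """Per-plot distance to the group center in the PCoA geometry."""

    plot_ids: list[str]
    groups: list[str]
    distances: np.ndarray
    center_type: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot": self.plot_ids,
                "group": self.groups,
                "distance_to_center": self.distances,
            }
        )


def pcoa_decompose(dm: DissimilarityMatrix) -> PCoAEmbedding:
    """Principal coordinates of a symmetric zero-diagonal dissimilarity matrix.

    Axes with |eigenvalue| < 1e-10 times the largest magnitude are dropped.
    Negative-eigenvalue axes are retained separately (no Lingoes/Cailliez
    correction), matching the uncorrected dispersion procedure.
    """
    D = dm.values
    n = D.shape[0]
    A = -0.5 * D * D
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    max_mag = np.max(np.abs(eigval), initial=0.0)
    keep = np.abs(eigval) > _EIG_REL_TOL * max_mag if max_mag > 0 else np.zeros(n, bool)
    eigval = eigval[keep]
    eigvec = eigvec[:, keep]

    pos = eigval > 0
    pos_axes = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_axes = eigvec[:, ~pos] * np.sqrt(-eigval[~pos])
    return PCoAEmbedding(list(dm.labels), pos_axes, neg_axes, eigval)


def _spatial_median(pos: np.ndarray, neg: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Weiszfeld iteration for the point minimising the sum of (clamped)
    signed distances; reduces to the geometric median when the negative
    block is empty."""
    c_pos = pos.mean(axis=0)
    c_neg = neg.mean(axis=0)
    for _ in range(max_iter):
        d2 = ((pos - c_pos) ** 2).sum(axis=1) - ((neg - c_neg) ** 2).sum(axis=1)
        d = np.sqrt(np.clip(d2, 0.0, None))
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum()
        new_pos = w @ pos
        new_neg = w @ neg
        shift = np.sqrt(((new_pos - c_pos) ** 2).sum() + ((new_neg - c_neg) ** 2).sum())
        c_pos, c_neg = new_pos, new_neg
        if shift < tol:
            break
    return c_pos, c_neg


def distance_to_center(
    emb: PCoAEmbedding,
    groups: list[str] | pd.Series,
    center_type: str = "centroid",
) -> DispersionResult:
    """Distance of every plot to its group's center.

    Squared distances are computed as the positive-block contribution minus
    the negative-block contribution; a negative result (possible for
    non-Euclidean input) is clamped to zero with a logged warning. Each
    group needs >= 2 plots.
    """
    if isinstance(groups, pd.Series):
        groups = [str(groups[p]) for p in emb.plot_ids]
    groups = [str(g) for g in groups]
    if len(groups) != emb.n_plots:
        raise ValueError("one group label per plot is required")
    if center_type not in ("centroid", "spatial_median"):
        raise ValueError(f"unknown center_type: {center_type!r}")

    labels = pd.unique(np.asarray(groups, dtype=object))
    distances = np.empty(emb.n_plots)
    n_clamped = 0
    for g in labels:
        idx = np.array([i for i, gg in enumerate(groups) if gg == g])
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 plots")
        pos = emb.positive_axes[idx]
        neg = emb.negative_axes[idx]
        if center_type == "centroid":
            c_pos = pos.mean(axis=0)
            c_neg = neg.mean(axis=0)
        else:
            c_pos, c_neg = _spatial_median(pos, neg)
        d2 = ((pos - c_pos) ** 2).sum(axis=1) - ((neg - c_neg) ** 2).sum(axis=1)
        n_clamped += int(np.sum(d2 < -1e-12))
        distances[idx] = np.sqrt(np.clip(d2, 0.0, None))
    if n_clamped:
        logger.warning(
            "%d negative squared distances clamped to 0 (non-Euclidean input)",
            n_clamped,
        )
    return DispersionResult(list(emb.plot_ids), groups, distances, center_type)
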