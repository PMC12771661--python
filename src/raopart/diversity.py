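"""Rao quadratic entropy partitioning: per-plot alpha, pooled-pair gamma,
and additively partitioned pairwise beta with the Jost equivalent-number
correction.

Rao's quadratic entropy for one community with relative abundances p and a
species dissimilarity matrix d is

    Q = sum_{i,j} d_ij * p_i * p_j,

the expected dissimilarity between two randomly drawn individuals. With the
taxonomic dissimilarity (d_ij = 1 for i != j) this reduces to the
Gini-Simpson index 1 - sum(p_i^2); with a unit-scaled cophenetic matrix it
is the phylogenetic facet. For each unordered plot pair, gamma is Q of the
pooled community and additive partitioning gives gamma = mean alpha + beta.
Because raw beta shrinks as alpha grows, both components are transformed to
equivalent numbers, 1/(1 - Q), before differencing (Jost correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import DissimilarityMatrix

__all__ = [
    "AbundanceTable",
    "DiversityResult",
    "taxonomic_dissimilarity",
    "relative_abundances",
    "rao_q",
    "pooled_gamma",
    "jost_equivalent",
    "alpha_diversity",
    "pairwise_beta",
]


@dataclass
class AbundanceTable:
    """Plots-by-species cover matrix (percent of plot surface, >= 0).

    Rows need not sum to 100; relative abundances are renormalised per plot
    wherever a diversity quantity is computed.
    """

    plot_ids: list[str]
    species: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.plot_ids = [str(x) for x in self.plot_ids]
        self.species = [str(x) for x in self.species]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.plot_ids)) != len(self.plot_ids):
            raise ValueError("duplicate plot ids")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if self.values.shape != (len(self.plot_ids), len(self.species)):
            raise ValueError("values shape does not match plot/species labels")
        if np.any(self.values < 0):
            raise ValueError("negative cover values")
        if np.any(self.values.sum(axis=1) <= 0):
            empty = [p for p, s in zip(self.plot_ids, self.values.sum(axis=1)) if s <= 0]
            raise ValueError(f"plots with zero total cover: {empty}")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.plot_ids, columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(
            [str(x) for x in df.index],
            [str(x) for x in df.columns],
            df.to_numpy(dtype=float),
        )

    def relative(self) -> np.ndarray:
        """Per-plot relative abundances (rows sum to 1)."""
        return self.values / self.values.sum(axis=1, keepdims=True)


@dataclass
class DiversityResult:
    """Alpha/beta/gamma components for one diversity facet.

    ``alpha`` is the per-plot Rao Q; the square matrices are plot-pairwise.
    ``beta`` (the default downstream response) follows the ``normalized``
    flag given to :func:`pairwise_beta`.
    """

    facet: str
    plot_ids: list[str]
    alpha: np.ndarray
    gamma_pairs: np.ndarray
    alpha_equiv_pairs: np.ndarray
    beta_add: np.ndarray
    beta_norm: np.ndarray
    jost: bool
    default_normalized: bool

    @property
    def beta(self) -> DissimilarityMatrix:
        vals = self.beta_norm if self.default_normalized else self.beta_add
        return DissimilarityMatrix(list(self.plot_ids), vals)

    def alpha_series(self) -> pd.Series:
        return pd.Series(self.alpha, index=self.plot_ids, name=f"alpha_{self.facet}")

    def beta_long(self) -> pd.DataFrame:
        """Long-format (plot_a, plot_b, facet, beta_add, beta_norm) table."""
        rows = []
        n = len(self.plot_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "plot_a": self.plot_ids[i],
                        "plot_b": self.plot_ids[j],
                        "facet": self.facet,
                        "beta_add": self.beta_add[i, j],
                        "beta_norm": self.beta_norm[i, j],
                    }
                )
        return pd.DataFrame(rows)


def taxonomic_dissimilarity(species: list[str]) -> DissimilarityMatrix:
    """Unit dissimilarity between distinct species: d_ij = 1 (i != j), else 0."""
    if len(species) < 1:
        raise ValueError("need at least one species")
    n = len(species)
    return DissimilarityMatrix(list(species), 1.0 - np.eye(n))


def relative_abundances(cover: np.ndarray) -> np.ndarray:
    """Normalise one plot's cover vector to proportions summing to 1."""
    cover = np.asarray(cover, dtype=float)
    if np.any(cover < 0):
        raise ValueError("negative cover")
    total = cover.sum()
    if total <= 0:
        raise ValueError("zero total cover")
    return cover / total


def rao_q(p: np.ndarray, d: DissimilarityMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``p`` and ``d`` must share the species ordering; with taxonomic d this
    equals the Gini-Simpson index 1 - sum(p_i^2).
    """
    p = np.asarray(p, dtype=float)
    dv = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)
    if dv.shape != (p.size, p.size):
        raise ValueError(f"dimension mismatch: p has {p.size}, d is {dv.shape}")
    return float(p @ dv @ p)


def pooled_gamma(
    p_a: np.ndarray,
    p_b: np.ndarray,
    d: DissimilarityMatrix | np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Q of the two-plot pooled community.

    Plots are pooled with equal weight by default — the plots are
    equal-area quadrats — i.e. pooled proportions (p_a + p_b) / 2.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("plots must share the species ordering")
    w_a, w_b = weights
    pooled = (w_a * p_a + w_b * p_b) / (w_a + w_b)
    return rao_q(pooled, d)


def jost_equivalent(q: float) -> float:
    """Equivalent-number transform 1 / (1 - Q), defined for 0 <= Q < 1."""
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    if q >= 1:
        raise ValueError(f"Q must be < 1 for the equivalent-number transform, got {q}")
    return 1.0 / (1.0 - q)


def _resolve_distance(
    table: AbundanceTable, d: DissimilarityMatrix | None
) -> np.ndarray:
    """Align a species distance matrix to the table's species order."""
    if d is None:
        return 1.0 - np.eye(table.n_species)
    missing = sorted(set(table.species) - set(d.labels))
    if missing:
        raise KeyError(
            f"species in abundance table absent from dissimilarity matrix: {missing}"
        )
    return d.subset(table.species).values


def alpha_diversity(
    table: AbundanceTable, d: DissimilarityMatrix | None = None
) -> pd.Series:
    """Per-plot Rao Q. ``d=None`` selects the taxonomic facet."""
    dv = _resolve_distance(table, d)
    P = table.relative()
    q = np.einsum("ks,st,kt->k", P, dv, P)
    facet = "taxonomic" if d is None else "phylogenetic"
    return pd.Series(q, index=table.plot_ids, name=f"alpha_{facet}")


def pairwise_beta(
    table: AbundanceTable,
    d: DissimilarityMatrix | None = None,
    jost: bool = True,
    normalized: bool = True,
    facet: str | None = None,
    pooling_weights: str = "equal",
) -> DiversityResult:
    """Additive alpha/beta/gamma partition over all unordered plot pairs.

    For each pair (a, b): alpha-bar = mean(Q_a, Q_b) and Q_gamma is Rao Q of
    the pooled pair. With ``jost`` on, both are converted to equivalent
    numbers before differencing:

        beta_add  = 1/(1 - Q_gamma) - 1/(1 - alpha-bar)
        beta_norm = beta_add / (1/(1 - Q_gamma))

    ``beta_norm`` lies in [0, 1) and is the default dissimilarity handed to
    the dispersion stage. With ``jost`` off, beta_add = Q_gamma - alpha-bar
    (raw scale) and beta_norm divides by Q_gamma.

    ``pooling_weights='abundance'`` pools proportional to each plot's total
    recorded cover instead of equally.
    """
    if table.n_plots < 2:
        raise ValueError("pairwise beta needs at least 2 plots")
    dv = _resolve_distance(table, d)
    P = table.relative()
    n = table.n_plots

    if pooling_weights == "equal":
        w = np.full(n, 0.5)
    elif pooling_weights == "abundance":
        w = table.values.sum(axis=1)
    else:
        raise ValueError(f"unknown pooling_weights: {pooling_weights!r}")

    # M[a, b] = p_a^T D p_b gives every alpha on the diagonal and every
    # pooled gamma via the quadratic expansion of the pooled proportions.
    M = P @ dv @ P.T
    q_alpha = np.diagonal(M).copy()

    wa = w[:, None]
    wb = w[None, :]
    denom = wa + wb
    gamma = (
        wa**2 * q_alpha[:, None] + 2 * wa * wb * M + wb**2 * q_alpha[None, :]
    ) / denom**2
    np.fill_diagonal(gamma, q_alpha)

    mean_alpha = (q_alpha[:, None] + q_alpha[None, :]) / 2.0

    if np.any(q_alpha >= 1) or np.any(gamma >= 1):
        raise ValueError("Rao Q reached 1; equivalent numbers undefined")

    if jost:
        alpha_eq = 1.0 / (1.0 - mean_alpha)
        gamma_eq = 1.0 / (1.0 - gamma)
        beta_add = gamma_eq - alpha_eq
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_norm = beta_add / gamma_eq
    else:
        alpha_eq = mean_alpha
        beta_add = gamma - mean_alpha
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_norm = np.where(gamma > 0, beta_add / np.where(gamma > 0, gamma, 1.0), 0.0)

    # concavity of Q keeps beta_add >= 0; clip the numerical dust
    beta_add = np.clip(beta_add, 0.0, None)
    beta_norm = np.nan_to_num(np.clip(beta_norm, 0.0, None), nan=0.0)
    np.fill_diagonal(beta_add, 0.0)
    np.fill_diagonal(beta_norm, 0.0)

    if facet is None:
        facet = "taxonomic" if d is None else "phylogenetic"
    return DiversityResult(
        facet=facet,
        plot_ids=list(table.plot_ids),
        alpha=q_alpha,
        gamma_pairs=gamma,
        alpha_equiv_pairs=alpha_eq,
        beta_add=beta_add,
        beta_norm=beta_norm,
        jost=jost,
        default_normalized=normalized,
    )
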