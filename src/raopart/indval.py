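"""Dufrene-Legendre indicator species analysis (IndVal) for site groups.

For each species and group g:

* specificity  A_g = mean cover in g / sum over groups of mean cover
  (group-size-corrected; the classic sum-based variant is available),
* fidelity     B_g = fraction of g's plots where the species occurs,
* IndVal_g     sqrt(A_g * B_g), and the species' statistic is the maximum
  over groups.

Significance comes from permuting group labels over plots; the same
permutations are shared across species so the test is a single
vectorised pass. Retention additionally applies abundance/occurrence
filters (defaults A >= 0.6, B >= 0.25) on top of the permutation p-value.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .diversity import AbundanceTable

__all__ = ["indval_stat", "indval_test", "filter_indicators", "significance_stars"]

logger = logging.getLogger(__name__)


def _group_matrix(groups: list[str]) -> tuple[np.ndarray, list[str]]:
    """Indicator matrix (n_groups x n_plots) and group label order."""
    labels = list(pd.unique(np.asarray(groups, dtype=object)))
    G = np.array([[1.0 if g == lab else 0.0 for g in groups] for lab in labels])
    return G, labels


def _indval_components(
    X: np.ndarray, G: np.ndarray, specificity: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A (groups x species), B, stat for a cover matrix X (plots x species)."""
    sizes = G.sum(axis=1)[:, None]
    mean_cover = (G @ X) / sizes
    if specificity == "mean":
        totals = mean_cover.sum(axis=0, keepdims=True)
    elif specificity == "sum":
        mean_cover = G @ X  # classic variant: group sums, not means
        totals = mean_cover.sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown specificity variant: {specificity!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(totals > 0, mean_cover / np.where(totals > 0, totals, 1.0), 0.0)
    B = (G @ (X > 0)) / sizes
    return A, B, np.sqrt(A * B)


def indval_stat(
    table: AbundanceTable,
    groups: list[str] | pd.Series,
    specificity: str = "mean",
) -> pd.DataFrame:
    """Observed IndVal components per species.

    Returns a frame indexed by species with columns ``A``, ``B``, ``stat``
    and ``best_group`` (ties broken toward the first group in input order,
    logged). Species with zero total cover are excluded with a warning.
    """
    if isinstance(groups, pd.Series):
        groups = [str(groups[p]) for p in table.plot_ids]
    groups = [str(g) for g in groups]
    if len(groups) != table.n_plots:
        raise ValueError("one group label per plot is required")
    G, labels = _group_matrix(groups)
    if len(labels) < 2:
        raise ValueError("at least 2 groups are required")

    X = table.values
    nonzero = X.sum(axis=0) > 0
    if not np.all(nonzero):
        dropped = [s for s, keep in zip(table.species, nonzero) if not keep]
        warnings.warn(f"excluding {len(dropped)} species with zero total cover")
        logger.warning("indval: excluded zero-cover species %s", dropped)
    species = [s for s, keep in zip(table.species, nonzero) if keep]
    X = X[:, nonzero]

    A, B, stat = _indval_components(X, G, specificity)
    best = stat.argmax(axis=0)  # argmax takes the first maximal group on ties
    ties = (stat == stat.max(axis=0, keepdims=True)).sum(axis=0) > 1
    if ties.any():
        logger.info(
            "indval: %d species tie between groups; first group in input "
            "order reported", int(ties.sum())
        )
    cols = np.arange(len(species))
    return pd.DataFrame(
        {
            "best_group": [labels[b] for b in best],
            "A": A[best, cols],
            "B": B[best, cols],
            "stat": stat[best, cols],
        },
        index=pd.Index(species, name="species"),
    )


def indval_test(
    table: AbundanceTable,
    groups: list[str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    specificity: str = "mean",
) -> pd.DataFrame:
    """IndVal with a permutation p-value per species.

    p = (1 + #{permuted max-over-groups stat >= observed stat}) / (n_perm + 1),
    permuting group labels over plots; the observed labelling counts as one
    permutation, so the smallest attainable p is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = indval_stat(table, groups, specificity=specificity)
    if isinstance(groups, pd.Series):
        groups = [str(groups[p]) for p in table.plot_ids]
    groups = [str(g) for g in groups]
    G, _ = _group_matrix(groups)
    X = table.values[:, [table.species.index(s) for s in obs.index]]

    if rng is None:
        rng = np.random.default_rng(seed)
    observed = obs["stat"].to_numpy()
    exceed = np.zeros(observed.size, dtype=int)
    n_plots = len(groups)
    for _ in range(n_perm):
        perm = rng.permutation(n_plots)
        _, _, stat = _indval_components(X, G[:, perm], specificity)
        exceed += stat.max(axis=0) >= observed - 1e-12
    out = obs.copy()
    out["p_value"] = (1.0 + exceed) / (n_perm + 1.0)
    return out


def filter_indicators(
    results: pd.DataFrame,
    min_A: float = 0.6,
    min_B: float = 0.25,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Apply the significance + abundance/occurrence retention rule.

    A species is retained iff p < alpha_level AND A >= min_A AND B >= min_B.
    The occurrence clause is read as "relative occurrence below 0.25
    excludes", parallel to the abundance clause.
    """
    logger.info(
        "indicator filter: p < %s, specificity A >= %s, fidelity B >= %s",
        alpha_level, min_A, min_B,
    )
    out = results.copy()
    out["retained"] = (
        (out["p_value"] < alpha_level) & (out["A"] >= min_A) & (out["B"] >= min_B)
    )
    return out


def significance_stars(p: float) -> str:
    """Conventional footnote stars: *, **, *** at 0.05/0.01/0.001; else n.s."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
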