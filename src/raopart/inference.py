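"""Regression and variance-partitioning statistics for the diversity
responses.

The central model is an ordinary least squares fit of a per-plot diversity
response on expansive-species cover, the two-level management factor
(reference level: abandoned) and their interaction:

    y = b0 + b1 * cover + b2 * I(mown) + b3 * cover * I(mown) + e.

Hierarchical partitioning then decomposes the full model's goodness of fit
into each predictor's independent contribution by averaging the improvement
it brings over all subsets at each hierarchy level (Chevan-Sutherland;
equivalent to averaging sequential improvements over all predictor
orderings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "HierPartResult",
    "fit_interaction_model",
    "hierarchical_partition",
    "unpaired_ttest",
    "fold_aspect",
    "standardize",
]


@dataclass
class ModelFit:
    """OLS fit summary for the cover x management interaction model."""

    terms: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r2: float
    adjusted_r2: float  # percent
    aic: float
    model_p_value: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    n_obs: int = 0

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def pval(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "p_value": self.p_values,
            },
            index=self.terms,
        )

    def diagnostics(self) -> pd.DataFrame:
        """Residual-vs-fitted and normal-QQ data for graphical checks."""
        resid = self.residuals
        sd = resid.std(ddof=1)
        order = np.argsort(resid)
        n = resid.size
        theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        qq_theoretical = np.empty(n)
        qq_theoretical[order] = theo
        return pd.DataFrame(
            {
                "fitted": self.fitted,
                "residual": resid,
                "std_residual": resid / sd if sd > 0 else resid,
                "qq_theoretical": qq_theoretical,
            }
        )


def _gaussian_aic(rss: float, n: int, k_coefficients: int) -> float:
    """AIC with the Gaussian log-likelihood convention that counts the
    error variance as a fitted parameter: n(log(2*pi) + log(RSS/n) + 1)
    + 2(k + 1)."""
    return n * (np.log(2 * np.pi) + np.log(rss / n) + 1) + 2 * (k_coefficients + 1)


def fit_interaction_model(
    y: np.ndarray | pd.Series,
    cover: np.ndarray | pd.Series,
    management: list[str] | pd.Series,
    reference: str = "abandoned",
    standardize_response: bool = False,
) -> ModelFit:
    """OLS of a diversity response on cover, management, and interaction.

    ``management`` must have exactly two levels, both present; the
    non-reference level (default: mown) gets the dummy. With
    ``standardize_response`` the response is z-scored first (coefficients
    change scale; R-squared does not).
    """
    y = np.asarray(y, dtype=float)
    cover = np.asarray(cover, dtype=float)
    management = [str(m) for m in management]
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not (cover.size == n and len(management) == n):
        raise ValueError("y, cover, and management must have equal length")
    levels = sorted(set(management))
    if len(levels) != 2:
        raise ValueError(f"management must have exactly 2 levels, got {levels}")
    if reference not in levels:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]

    if standardize_response:
        y = standardize(y)

    dummy = np.array([1.0 if m == other else 0.0 for m in management])
    X = np.column_stack([np.ones(n), cover, dummy, cover * dummy])
    terms = ["intercept", "cover", f"management[{other}]", f"cover:management[{other}]"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    k = X.shape[1]
    adj = 100.0 * res.rsquared_adj
    return ModelFit(
        terms=terms,
        coefficients=np.asarray(res.params, dtype=float),
        std_errors=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        r2=float(res.rsquared),
        adjusted_r2=adj,
        aic=_gaussian_aic(rss, n, k),
        model_p_value=float(res.f_pvalue),
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        n_obs=n,
    )


@dataclass
class HierPartResult:
    """Independent (I) and joint (J) contributions per predictor.

    Contributions carry the units of the chosen goodness of fit (here
    reported as R-squared in percent). With gof = R2 the independent
    contributions sum exactly to the full-model R2; with adjusted R2 the
    identity holds only approximately.
    """

    predictors: list[str]
    independent: np.ndarray  # percent
    joint: np.ndarray  # percent
    gof_full: float  # percent
    gof: str

    @property
    def relative(self) -> np.ndarray:
        """Shares I_k / sum(I) in percent."""
        total = self.independent.sum()
        return 100.0 * self.independent / total if total != 0 else self.independent * 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "independent": self.independent,
                "joint": self.joint,
                "relative": self.relative,
            },
            index=pd.Index(self.predictors, name="predictor"),
        )


def _subset_gof(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...], gof: str) -> float:
    n = y.size
    design = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if gof == "r2":
        return r2
    if gof == "adjr2":
        p = len(cols)
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    raise ValueError(f"unknown gof: {gof!r}")


def hierarchical_partition(
    y: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    gof: str = "r2",
) -> HierPartResult:
    """All-subsets decomposition of explained variance.

    Fits all 2^k subsets of predictors; predictor k's independent
    contribution I_k is the average — over hierarchy levels, then over the
    subsets within a level — of the goodness-of-fit improvement from adding
    k. The joint contribution is J_k = gof({k}) - I_k. Limited to k <= 12
    predictors (combinatorial guard).
    """
    y = np.asarray(y, dtype=float)
    names = list(predictors.columns)
    k = len(names)
    if not 1 <= k <= 12:
        raise ValueError(f"between 1 and 12 predictors required, got {k}")
    X = predictors.to_numpy(dtype=float)

    gof_cache: dict[tuple[int, ...], float] = {(): 0.0}
    if gof == "adjr2":
        gof_cache[()] = 0.0  # empty model explains nothing by convention
    for r in range(1, k + 1):
        for cols in combinations(range(k), r):
            gof_cache[cols] = _subset_gof(y, X, cols, gof)

    independent = np.zeros(k)
    for j in range(k):
        others = [c for c in range(k) if c != j]
        level_means = []
        for r in range(0, k):  # size of the subset j is added to
            imps = []
            for cols in combinations(others, r):
                with_j = tuple(sorted(cols + (j,)))
                imps.append(gof_cache[with_j] - gof_cache[cols])
            level_means.append(np.mean(imps))
        independent[j] = np.mean(level_means)

    singles = np.array([gof_cache[(j,)] for j in range(k)])
    joint = singles - independent
    full = gof_cache[tuple(range(k))]
    return HierPartResult(
        predictors=names,
        independent=100.0 * independent,
        joint=100.0 * joint,
        gof_full=100.0 * full,
        gof=gof,
    )


def unpaired_ttest(
    x1: np.ndarray, x2: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test (pooled variance by default; Welch as option).

    Returns (t, df, two-sided p). Zero pooled variance is a degenerate
    input and raises rather than returning an infinite statistic.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x1, ddof=1) == 0 and np.var(x2, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x1, x2, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_aspect(aspect: float | np.ndarray) -> float | np.ndarray:
    """Fold compass aspect onto a north(0)-south(180) linear scale.

    East and west map symmetrically: 180 - |180 - aspect|.
    """
    a = np.asarray(aspect, dtype=float)
    if np.any(a < 0) or np.any(a > 360):
        raise ValueError("aspect must lie in [0, 360] degrees")
    folded = 180.0 - np.abs(180.0 - a)
    return float(folded) if np.isscalar(aspect) or folded.ndim == 0 else folded


def standardize(y: np.ndarray | pd.Series) -> np.ndarray:
    """Z-score: zero mean, unit sample standard deviation."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; cannot standardize a constant vector")
    return (y - y.mean()) / sd
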