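"""Interaction regression, hierarchical partitioning, t-test, helpers."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from raopart.inference import (
    fit_interaction_model,
    fold_aspect,
    hierarchical_partition,
    standardize,
    unpaired_ttest,
)


def make_design(rng, n=40):
    cover = rng.uniform(0, 80, n)
    management = list(rng.permutation(["mown"] * (n // 2) + ["abandoned"] * (n - n // 2)))
    return cover, management


class TestInteractionModel:
    def test_exact_linear_recovery(self, rng):
        cover, mgmt = make_design(rng)
        dummy = np.array([m == "mown" for m in mgmt], dtype=float)
        y = 1.0 + 0.5 * cover - 2.0 * dummy + 0.0 * cover * dummy
        fit = fit_interaction_model(y, cover, mgmt)
        assert fit.coef("intercept") == pytest.approx(1.0, abs=1e-10)
        assert fit.coef("cover") == pytest.approx(0.5, abs=1e-10)
        assert fit.coef("management[mown]") == pytest.approx(-2.0, abs=1e-10)
        assert fit.coef("cover:management[mown]") == pytest.approx(0.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_aic_matches_r_convention(self, rng):
        """AIC = n(log(2 pi) + log(RSS/n) + 1) + 2(k+1), the convention of
        R's AIC() for lm objects."""
        cover, mgmt = make_design(rng)
        y = rng.normal(size=len(cover))
        fit = fit_interaction_model(y, cover, mgmt)
        n = len(y)
        rss = np.sum(fit.residuals**2)
        expected = n * (np.log(2 * np.pi) + np.log(rss / n) + 1) + 2 * 5
        assert fit.aic == pytest.approx(expected, abs=1e-9)

    def test_pure_noise_adjusted_r2_near_zero(self, rng):
        """Adjusted R2 is unbiased near 0 for a null response."""
        vals = []
        for _ in range(300):
            cover, mgmt = make_design(rng, n=60)
            y = rng.normal(size=60)
            vals.append(fit_interaction_model(y, cover, mgmt).adjusted_r2)
        assert abs(np.mean(vals)) < 2.0  # percent

    def test_interaction_type_i_error_calibrated(self, rng):
        """With no true interaction, the interaction term rejects at ~5%."""
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            cover, mgmt = make_design(rng, n=50)
            dummy = np.array([m == "mown" for m in mgmt], dtype=float)
            y = 1.0 - 0.02 * cover + 0.5 * dummy + rng.normal(size=50)
            fit = fit_interaction_model(y, cover, mgmt)
            rejections += fit.pval("cover:management[mown]") < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 0.03

    def test_r2_invariant_to_response_standardization(self, rng):
        cover, mgmt = make_design(rng)
        y = rng.normal(size=len(cover)) + 0.01 * cover
        f1 = fit_interaction_model(y, cover, mgmt)
        f2 = fit_interaction_model(y, cover, mgmt, standardize_response=True)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)
        assert f2.coef("cover") == pytest.approx(
            f1.coef("cover") / np.std(y, ddof=1), abs=1e-10
        )

    def test_single_level_management_rejected(self, rng):
        cover = rng.uniform(0, 50, 10)
        with pytest.raises(ValueError, match="2 levels"):
            fit_interaction_model(rng.normal(size=10), cover, ["mown"] * 10)

    def test_rank_deficiency_rejected(self):
        cover = np.array([10.0] * 6)  # constant cover: interaction collinear
        mgmt = ["mown"] * 3 + ["abandoned"] * 3
        with pytest.raises(ValueError, match="rank"):
            fit_interaction_model(np.arange(6.0), cover, mgmt)


def all_orderings_partition(y, X):
    """Oracle: average sequential R2 improvements over all k! orderings."""
    k = X.shape[1]

    def r2(cols):
        if not cols:
            return 0.0
        d = np.column_stack([np.ones(len(y))] + [X[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        resid = y - d @ beta
        return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

    contrib = np.zeros(k)
    orderings = list(permutations(range(k)))
    for order in orderings:
        cols = []
        for c in order:
            before = r2(tuple(cols))
            cols.append(c)
            contrib[c] += r2(tuple(cols)) - before
    return contrib / len(orderings)


class TestHierarchicalPartition:
    def test_orthogonal_predictors_no_joint(self, rng):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2 * x1 + 1 * x2 + rng.normal(scale=0.1, size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        res = hierarchical_partition(y, X)
        # orthogonal: independent contribution equals the single-predictor R2
        assert np.allclose(res.joint, 0.0, atol=1e-8)

    def test_duplicate_predictor_splits_evenly(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        X = pd.DataFrame({"x1": x, "x2": x.copy()})
        res = hierarchical_partition(y, X)
        assert res.independent[0] == pytest.approx(res.gof_full / 2, abs=1e-8)
        assert res.independent[1] == pytest.approx(res.gof_full / 2, abs=1e-8)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_all_orderings_oracle(self, rng, k):
        n = 25
        X = rng.normal(size=(n, k)) @ (np.eye(k) + 0.4)  # correlated predictors
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        res = hierarchical_partition(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(k)]))
        oracle = all_orderings_partition(y, X)
        assert np.allclose(res.independent, 100 * oracle, atol=1e-10)

    def test_independent_contributions_sum_to_full_r2(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 6))
            n = 20 + k
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            res = hierarchical_partition(
                y, pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
            )
            assert res.independent.sum() == pytest.approx(res.gof_full, abs=1e-8)

    def test_k_guard(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 13)))
        X.columns = [f"x{i}" for i in range(13)]
        with pytest.raises(ValueError, match="12"):
            hierarchical_partition(rng.normal(size=20), X)


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = unpaired_ttest(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            unpaired_ttest(np.zeros(4), np.ones(4))

    def test_pooled_df(self, rng):
        t, df, p = unpaired_ttest(rng.normal(size=10), rng.normal(size=12))
        assert df == pytest.approx(20)

    def test_power_matches_monte_carlo(self, rng):
        """N(0,1) vs N(1,1) with n=30+31: empirical rejection at alpha=0.01
        is self-consistent across two independent batches (+- 3%)."""

        def batch():
            hits = 0
            for _ in range(300):
                _, _, p = unpaired_ttest(
                    rng.normal(size=30), rng.normal(loc=1.0, size=31)
                )
                hits += p < 0.01
            return hits / 300

        assert abs(batch() - batch()) < 0.09
        # and the power is high, as expected for d=1 at these sizes
        assert batch() > 0.85


class TestHelpers:
    @pytest.mark.parametrize(
        "aspect,folded",
        [(0, 0), (360, 0), (180, 180), (333, 27), (290, 70), (90, 90), (270, 90)],
    )
    def test_fold_aspect(self, aspect, folded):
        assert fold_aspect(aspect) == pytest.approx(folded)

    def test_fold_aspect_domain(self):
        with pytest.raises(ValueError):
            fold_aspect(400)

    def test_standardize(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_standardize_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.full(5, 3.0))
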