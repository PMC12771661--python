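# Methods

## Diversity model

Alpha diversity is Rao's quadratic entropy `Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ` computed on
within-plot relative covers. The taxonomic facet uses `dᵢⱼ = 1` for `i ≠ j`,
so `Q = 1 − Σ pᵢ²` (the Gini–Simpson index). Presentations of this quantity
sometimes label `Σ pᵢ²` itself "Simpson diversity"; we always report the
concave form `1 − Σ pᵢ²`, which is what Rao's Q with unit distances equals
and what the equivalent-number transform expects. The phylogenetic facet
replaces `d` with the cophenetic (patristic) distance matrix of a rooted,
branch-length-bearing tree, divided by its global maximum so both facets
share the [0, 1] scale and `Q_phy ≤ Q_tax` holds plot-wise.

Unit scaling is performed **once**, on the distance matrix of the full
species list, not per analysis subset. Rescaling per subset would make Q
values incomparable across plots whenever the subset maximum changes; the
choice is recorded in the run log (`scale_distance_once`).

Beta diversity is partitioned per unordered plot pair. Gamma is Q of the
pooled pair with **equal plot weights** (pooled proportions
`(p_a + p_b)/2`) because plots are equal-area quadrats; abundance-weighted
pooling is available (`pooling_weights="abundance"`). Since beta approaches
zero as alpha grows, alpha (the pair mean, not per-plot-then-averaged) and
gamma are converted to equivalent numbers `1/(1 − Q)` before differencing:

    β_add  = 1/(1 − γ) − 1/(1 − ᾱ),      β_norm = β_add · (1 − γ).

`β_norm ∈ [0, 1)` is the default pairwise dissimilarity handed to the
dispersion stage, because a bounded proportion behaves better as a
distance; `β_add` is always stored alongside and selectable (`--beta add`).

## Group dispersion

The β matrix is embedded by principal coordinates (Gower double-centering
of `−D∘D/2`, full eigendecomposition). β_norm is generally non-Euclidean,
so negative eigenvalues occur; their axes are kept as an imaginary block
and squared distances are computed as the positive-block contribution minus
the negative-block contribution, which reconstructs the input `D²` exactly
(checked to 1e-8 in tests). Squared distances to a group center that come
out negative are clamped to zero and logged — this keeps the response
defined; no Lingoes/Cailliez eigenvalue correction is applied by default.
Centers default to the group **centroid** (analytically checkable against
plain Euclidean geometry when the input is embeddable); a spatial-median
center (Weiszfeld iteration, tolerance 1e-10) is provided because
R implementations of the procedure have defaulted to either across
versions.

## Regression and partitioning

Each of the four responses (α TD, α PD, β-dispersion TD, β-dispersion PD)
is fit by OLS on `[1, cover, I(mown), cover × I(mown)]`, reference level
abandoned, so the management coefficient is the mown contrast at zero
cover. Responses are fit on their raw scale by default; `--standardize`
z-scores them first (R² and AIC-ranking are unaffected; coefficients
rescale). AIC uses the Gaussian convention that counts the error variance
as a parameter, `n(log 2π + log(RSS/n) + 1) + 2(k + 1)`, matching R's
`AIC()` for `lm`. Residual-vs-fitted and normal-QQ tables are exported via
`ModelFit.diagnostics()` for the usual graphical checks.

Hierarchical partitioning fits all `2^k` predictor subsets (guarded at
k ≤ 12) and averages each predictor's goodness-of-fit improvement within
hierarchy levels, then across levels (Chevan–Sutherland; identical to
averaging sequential improvements over all k! orderings, which the tests
verify by brute force). With gof = R² the independent contributions sum
exactly to the full-model R²; with adjusted R² (selectable, since
contribution tables are often printed on that scale) the identity is only
approximate, and the empty model is assigned gof 0 by convention. Relative
shares are `Iₖ/ΣIₖ · 100`; the reported "joint" column is the per-predictor
`Jₖ = gof({k}) − Iₖ` summed over predictors, which can be negative when a
suppressor relationship is present.

## Indicator species analysis

Specificity uses group **means** (size-corrected), appropriate for the
unbalanced 31/30 design; the classic sum-based variant is selectable.
The permutation p-value counts the observed labelling among the
permutations, `p = (1 + #{perm ≥ obs})/(n_perm + 1)` with 999 permutations
by default, shuffling labels over plots with one seeded generator shared
across species. Retention requires p < 0.05 **and** A ≥ 0.6 **and**
B ≥ 0.25; the occurrence clause is read as "below 0.25 excludes", parallel
to the abundance clause (the choice is logged at run time). Ties in the
best group go to the first group in input order, logged.

## Synthetic-community generator

The generator emulates the target design: 31 mown and 30 abandoned
quadrats, pools of 60 and 50 species sharing 60% of the smaller pool, one
expansive grass present in both pools' phylogeny. Mechanism per plot:

1. expansive cover `c ~ Uniform(0, 80)` (%), the same gradient in both
   managements so the fitted management terms reflect community structure,
   not sampling ranges;
2. subordinate richness `S = max(1, round(S₀ + b·c + ε))`,
   `ε ~ N(0, 1.5)`, with `S₀ = 28` (mown) vs. `10` (abandoned) — a
   species-rich regularly mown sward against a species-poor tussock-choked
   abandoned matrix — and slope `b = −0.15` (mown) vs. `−0.05`
   (abandoned) species per percent cover: the biotic filter is stronger
   where there are more species to exclude;
3. species drawn from the management's pool with weights
   `exp(−λ·d(species, expansive))` on unit-scaled cophenetic distance,
   `λ = 0` (mown) vs. `3` (abandoned), so abandoned communities are
   phylogenetically clustered around the expansive lineage;
4. covers: the expansive species gets exactly `c`; the remaining `100 − c`
   is split among subordinates by a symmetric Dirichlet(1) (neutral
   evenness; concentration exposed in the config).

Diversity is never targeted directly — it responds emergently through
richness reduction and cover monopolisation, so recovery experiments test
the whole causal chain. Phylogenies are Yule pure-birth trees,
ultrametricised by construction and scaled to unit depth. Metadata
(altitude, aspect, slope, litter) is drawn from management-conditional
normals with litter strongly elevated under abandonment.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring quadrats, temporally split sampling campaigns, observer error
in visual cover estimation, and rare-species occupancy patterns. Passing
recovery tests therefore demonstrate that the statistical machinery detects
the intended structure under idealised sampling, not that field data of
this size always yield significant effects.

## Numerical choices and edge cases

- Dissimilarity matrices must be symmetric to 1e-12 with zero diagonal;
  they are exactly symmetrised after validation.
- An all-zero distance matrix cannot be unit-scaled; it is returned
  unchanged with a warning.
- PCoA drops axes with |λ| < 1e-10 × max|λ|.
- `β_add` values are clipped at zero from below (concavity of Q guarantees
  non-negativity up to floating-point dust).
- Equivalent numbers require Q < 1; a plot pair reaching Q = 1 raises.
- The two-sample t-test refuses zero-variance input rather than returning
  an infinite statistic; Welch's correction is optional.
- Species present in the community table but absent from the tree are a
  hard error; `drop_missing_species=True` prunes them with a logged
  warning, since silent pruning changes Q.
- All randomness flows from one `numpy` Generator per entry point; the
  same seed reproduces datasets and permutation p-values byte-for-byte.

## Problem sizes used in validation

The test suite and acceptance script run: 200 replicate datasets of the
default 61-plot design for sign recovery; 150–200 null tables (16 plots ×
20 species, 199 permutations) for permutation-test calibration; 500
regression nulls for interaction type-I error; up to 1000 random instances
(k ≤ 5) for the partitioning sum identity; exhaustive 4+4-plot permutation
enumeration and k ≤ 4 all-orderings brute force as oracles. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances.
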