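# raopart

Diversity partitioning for grassland vegetation plots along an
expansive-species cover gradient. The package targets a recurring question
in management ecology: does regular mowing keep taxonomic and phylogenetic
diversity high by holding back an expansive tussock grass (a *biotic
filter*), and does the strength of that filter differ between mown and
abandoned swards? It is written for community ecologists who have a
plots-by-species percent-cover matrix, plot metadata (management class and
expansive-species cover), and a rooted phylogeny of the species pool.

## What it computes

**Alpha diversity** per plot is Rao's quadratic entropy

    Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ,

the expected dissimilarity between two randomly drawn individuals, where
`pᵢ` are within-plot relative abundances. With `dᵢⱼ = 1` for all distinct
species pairs (taxonomic facet) this reduces to the Gini–Simpson index
`1 − Σ pᵢ²`; with the tip-to-tip cophenetic distance matrix of the
phylogeny rescaled to [0, 1] it is the phylogenetic facet.

**Beta diversity** is partitioned additively per plot pair, `γ = mean α + β`,
where γ is Q of the pooled pair. Because raw β shrinks as α grows, both
components are transformed to equivalent numbers `1/(1 − Q)` (Jost
correction) before differencing; the default pairwise dissimilarity is the
normalised `β/γ` on the equivalent-number scale, bounded in [0, 1).

**Downstream inference**:

- *group dispersion* — principal-coordinate embedding of the β matrix
  (negative eigenvalues retained as an imaginary block) and each plot's
  distance to its management group's centroid, used as a univariate β
  response (`betadisper`-style);
- *interaction regression* — OLS of each diversity response on expansive
  cover, management (reference: abandoned) and their interaction;
- *hierarchical partitioning* — Chevan–Sutherland decomposition of model R²
  into independent and joint contributions per predictor;
- *indicator species analysis* — Dufrêne–Legendre IndVal `√(A·B)` with a
  label-permutation test and abundance/occurrence retention filters
  (A ≥ 0.6, B ≥ 0.25, p < 0.05).

A synthetic-community generator (`raopart.synth`) reproduces the study
design (61 quadrats of 0.5 × 0.5 m, 31 mown / 30 abandoned, partially
overlapping species pools of 60 and 50) with known ground truth, so the
whole pipeline can be validated by parameter-recovery experiments.

## Worked example

```bash
raopart simulate --seed 3 --out demo
raopart all --community demo/community.csv --metadata demo/metadata.csv \
            --tree demo/tree.nwk --seed 3 --out demo/results
```

`demo/results/models.tsv` then contains one row per response (this run's
actual output, rounded):

| index | facet | cover | management | interaction | adj. R² (%) | AIC |
|-------|-------|-------|-----------|-------------|------------|-----|
| alpha | TD | −0.0051*** | 0.166*** | −0.0023** | 86.9 | −164.5 |
| alpha | PD | −0.0050*** | 0.218*** | −0.0018*  | 83.1 | −141.1 |
| beta  | TD | −0.0039*** | −0.098** | 0.0014*   | 61.3 | −159.7 |
| beta  | PD | −0.0018*** | −0.068*  | 0.0013*   | 21.5 | −175.8 |

Read: alpha taxonomic diversity drops by ≈0.005 Rao-Q units per percent of
expansive cover, mown plots sit ≈0.17 units higher at zero cover, and the
negative interaction means the decline is steeper under mowing — the
expected signature when mowing maintains a species-rich sward that the
expansive grass then erodes. `hierpart.tsv` shows expansive cover
contributing far more independent explained variance than management
(92% vs. 8% of the partitioned R² for alpha TD in this run), and
`indval.tsv` lists the retained indicator species per management.

The per-plot α values are in `alpha.tsv` (e.g. `plot_01`, a mown plot with
72% expansive cover, has α-TD 0.469; `plot_02` at 40% cover has 0.811),
β matrices in `beta_*.tsv`, dispersion distances in `dispersion.tsv`, and
every file carries a `# config_hash=` header tying it to the options in
`run_log.yaml`.

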