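# Methods

## Model

The score of a gene set in a sample is a two-stage summary of a genes ×
samples expression matrix with a query condition (C1) and a reference
condition (C2). Stage one discretizes each gene against its own reference
behaviour: with μ_g the mean and σ_g the *population* standard deviation
(divisor 1/|C2|) of gene g over the reference samples, an expression value
v(g, s) becomes 1 iff v(g, s) > μ_g + σ_g. Stage two averages the bits over
a gene set: ES(s, GS) = (# member genes binarized 1 in s) / G. Scores
therefore live on the grid {0, 1/G, …, 1}.

Assumptions worth stating explicitly:

- Expression values are used as provided (the method is designed for
  normalized units such as RSEM/CPM); no internal log-transform or
  between-sample normalization is applied. The threshold is equivariant
  under per-gene affine maps applied to all samples, so gene-level scale
  differences do not matter, but sample-level normalization is the caller's
  responsibility.
- The reference condition must be homogeneous enough for μ_g + σ_g to be a
  meaningful "elevated expression" cut-off. With a single reference sample
  σ_g = 0 and the threshold degenerates to μ_g.
- σ_g = 0 genes (constant reference) are kept; they binarize 1 iff
  v > μ_g.
- Values exactly at the threshold map to 0 (strict inequality).
- Finiteness is enforced; negativity is not. Normalized expression is
  non-negative in practice, but two of the package's own protocols
  (unclamped additive Gaussian noise, Gaussian null-calibration inputs)
  legitimately produce negative values, so the container accepts them.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `denominator` | `measured` | Divide hit counts by the member genes present in the matrix. `full` uses the literal set size G, which deflates scores of sets with unmeasured genes irrespective of biology; it is provided for strict comparability. |
| `score_samples` | `query` | Score only C1 samples; `all` also scores the reference cells (needed in one-vs-rest mode, where every cell gets a score against the complement's statistics). |
| permutation `n` | 1000 | Label permutations; p = #{ES_perm ≥ ES_obs}/n. The exact formula can return 0; the corrected (count+1)/(n+1) value is always reported alongside and never silently substituted. |
| permutation `statistic` | `mean` | Aggregates per-sample ES of the permuted C1 into one dataset-level statistic. The aggregation is a genuine design choice (a per-sample score has no unique dataset-level summary); mean is the default, median or a callable may be passed. |
| noise `mean`, `sd` | 0.01, grid 0.01–0.06 | Additive Gaussian noise for robustness experiments, applied to every entry of the matrix (both conditions). No clamping at zero by default (literal addition); `clamp=True` exists for count-like downstream use. The grid targets normalized log-scale expression units; the sd is a free parameter. |
| `dropout_rate` | 0.0 | Single-cell simulation: iid Bernoulli zero-masking per entry. |
| `effect_size` (δ) | 2.0 | Planted activation, in units of each member gene's SD, added to C1 samples only. At δ the expected per-gene hit rate is Φ(δ − 1), e.g. ≈ 0.84 at δ = 2 — a useful sanity anchor for simulations. |

## One-vs-rest mode

For each cell type t, the reference condition is "all cells not of type t";
reference statistics come from that complement, *all* cells (including the
reference ones) are binarized against them, and t's signature is scored in
every cell. This convention — scoring reference cells against the
complement's statistics rather than excluding them — is one reading of the
workflow and is the one adopted here, because downstream in-type vs
out-of-type comparisons (fold change of mean scores) need both groups
scored on the same scale. The fold change is mean(in-type) / mean(out),
with conventions +∞ when the out-group mean is 0 and the in-group is not,
and 1 when both are 0.

## Permutation significance and null calibration

Each permutation reshuffles the label vector uniformly (preserving group
sizes) and recomputes the entire pipeline — reference statistics included —
so the null distribution reflects the full estimation procedure. One master
seed drives per-set streams derived via `SeedSequence`, making every
p-value bit-reproducible.

The calibration harness shuffles the labels n_perm times and runs a full
inner permutation test in each shuffled dataset, giving a (sets × n_perm)
null p-value matrix. Pooled p-values are compared with Uniform(0,1) two
ways: a KS test on the exact p-values, and a quantile-quantile summary —
sorted p paired with plotting positions (i − 0.5)/N, binned into 100
equal-width bins, mean observed vs expected −log10(p) per bin, and a
through-the-origin regression slope. The −log10 summaries use the corrected
p-values because the exact formula can yield p = 0; empty bins are flagged
in the report, never dropped silently. If fewer than 100 pooled p-values
exist, binning coarsens with a warning and the bin count is recorded.

A real limitation: the ES statistic is discrete, so with small gene sets
or few samples, ties between observed and permuted statistics make the
one-sided "≥" p-value conservatively biased, and strict uniformity fails
no matter how correct the implementation. Calibration experiments should
use set sizes and sample counts large enough that the statistic is close to
continuous. The package's own validation uses 3000 genes, 25+25 samples,
50 sets of 100 genes and 200 × 300 permutations, where pooled null
p-values pass KS uniformity at α = 0.01 with a QQ slope within [0.9, 1.1].

## Synthetic data

The generators emulate the structure the method consumes, not any real
dataset: per-gene baseline means are log-normal (natural-log mean 1.5, sd
0.6 by default — right-skewed abundances around ~4.5 units), per-gene SDs
are a uniform 15–35% coefficient of variation, values are Gaussian around
the baseline truncated at zero, and planted sets shift their member genes
by δ·σ_g in C1 only. Planted and decoy sets are disjoint. Dropout is
uniform Bernoulli masking — real single-cell dropout is
expression-dependent, so passing dropout tests here shows robustness to
zero-inflation, not to the selection bias of real capture. Pseudobulk
aggregation sums per-gene values across the cells of each assigned sample
and conserves per-gene totals; a mixed-label pseudobulk sample takes the
majority label with a warning.

What passing on these simulations does **not** show: robustness to
sample-level batch effects, to normalization differences between
conditions, or to correlated gene–gene structure (genes are simulated
independently).

## Evaluation metrics

ARI and silhouette delegate to scikit-learn. ARI is returned as-is and can
be negative for worse-than-chance partitions (some texts describe its range
as [0, 1]; that is only the typical range). Silhouette uses Euclidean
distance over enrichment scores by default (metric configurable); size-1
clusters contribute 0. Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN),
balanced accuracy their mean; a zero denominator yields NaN with a warning
rather than a fabricated rate. Multi-class clusterings are reduced to
binary counts by matching clusters to classes with a Hungarian assignment
on the contingency table, then per-class one-vs-rest counts and
macro-averaging — one interpretation among several, chosen because it is
deterministic and label-permutation invariant. Min-max scaling maps a
constant vector to all zeros with a warning. The coefficient of variation
uses the *sample* (n−1) SD — deliberately different from the population σ_g
of the binarization step, as the two serve different roles.

## Numerical and interface choices

- Population σ via `ddof=0`; this diverges from the `ddof=1` default of
  most libraries and is covered by explicit tests.
- Duplicate gene or sample identifiers are errors, never silently
  aggregated; identifier matching is case-sensitive unless `fold_case` is
  requested.
- Sets with no measured genes are dropped with a warning and listed in the
  output metadata; an entirely unmeasured collection is an error.
- Output orientation is fixed as sets × samples with a sample-identifier
  header; the JSON sidecar records denominator mode, measured counts and
  dropped sets.
- CLI: stochastic subcommands generate and record a seed when none is
  given; outputs are never overwritten without `--force`; logs go to
  stderr; exit codes distinguish usage (2), parse (3) and
  computation/configuration (4) failures.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at desk scale: 50
random instances of ≤30 genes × ≤15 samples × ≤5 sets for exact-equivalence
checks against naive loop implementations; a 6-sample dataset for
Monte-Carlo vs exhaustive (C(6,3) = 20) permutation comparison; the
calibration conditions above; 20 replicates per effect size for planted-set
recovery (δ ∈ {0, 0.5, 1, 2, 5}); and a 300-gene, 20+20-sample matrix with
per-gene σ ≥ 1.5 for the additive-noise protocol. These sizes keep the full
validation in the low minutes while exercising every code path at
statistically meaningful scale.
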